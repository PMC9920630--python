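"""Multi-test feature relevance ranking with rank-sum voting.

Three filter statistics — chi-square, one-way ANOVA F and mutual
information — each order the 15 features from most to least relevant for
a given target (the 4-class quadrant label or one one-vs-rest quadrant
indicator); a Borda rank-sum vote combines the three orders into the
final ranking used to pick feature subsets for model building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as _chi2, f_classif, mutual_info_classif

from .features import FEATURE_NAMES, FeatureTable
from .quadrants import QuadrantLabel

__all__ = [
    "FeatureRanking",
    "rank_chi2",
    "rank_anova_f",
    "rank_mutual_info",
    "vote",
    "one_vs_rest_labels",
    "rank_features",
]


@dataclass
class FeatureRanking:
    """Features ordered from most to least relevant, with their scores."""

    ordered: list  # list of (feature_name, score)
    source: str

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ordered]

    def top(self, k: int) -> list[str]:
        return self.names[:k]

    def position(self, name: str) -> int:
        """1-based rank (1 = most relevant)."""
        return self.names.index(name) + 1


def _labels_array(table: FeatureTable, labels) -> np.ndarray:
    y = labels if labels is not None else table.labels
    return np.asarray([lab.value if isinstance(lab, QuadrantLabel) else lab for lab in y])


def _order(scores: np.ndarray, names: Sequence[str], source: str) -> FeatureRanking:
    scores = np.where(np.isnan(scores), 0.0, scores)
    # Descending score, ties broken lexicographically for determinism.
    idx = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return FeatureRanking(ordered=[(names[i], float(scores[i])) for i in idx], source=source)


def rank_chi2(table: FeatureTable, labels=None) -> FeatureRanking:
    """Rank features by the chi-square statistic of per-class feature mass.

    Requires non-negative (normalized) feature values.
    """
    if (table.data.values < 0).any():
        raise ValueError("chi-square ranking requires non-negative features; normalize the table first")
    scores, _ = _chi2(table.data.values, _labels_array(table, labels))
    return _order(scores, list(table.data.columns), "chi2")


def rank_anova_f(table: FeatureTable, labels=None) -> FeatureRanking:
    """Rank features by the one-way ANOVA F statistic (between/within
    variance ratio)."""
    y = _labels_array(table, labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("ANOVA-F ranking needs >= 2 classes with >= 2 rows each")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant filler columns legitimately score 0; silence the notice
        warnings.simplefilter("ignore", UserWarning)
        scores, _ = f_classif(table.data.values, y)
    scores = np.where(np.isinf(scores), np.finfo(float).max, scores)
    return _order(scores, list(table.data.columns), "anova_f")


def rank_mutual_info(table: FeatureTable, labels=None, seed: int = 0) -> FeatureRanking:
    """Rank features by estimated mutual information with the label
    (nearest-neighbour estimator; seeded, hence deterministic)."""
    scores = mutual_info_classif(table.data.values, _labels_array(table, labels), random_state=seed)
    return _order(scores, list(table.data.columns), "mutual_info")


def vote(rankings: Sequence[FeatureRanking]) -> FeatureRanking:
    """Borda rank-sum aggregation of several rankings.

    The combined score of a feature is the sum of its 1-based positions
    across the input rankings (lower = more relevant).  Ties are broken by
    the ANOVA-F ranking when one of the inputs is ANOVA-F, then by name.
    """
    if not rankings:
        raise ValueError("need at least one ranking to vote")
    names = set(rankings[0].names)
    for r in rankings[1:]:
        if set(r.names) != names:
            raise ValueError("rankings cover different feature sets")
    rank_sum = {name: sum(r.position(name) for r in rankings) for name in names}
    anova = next((r for r in rankings if r.source == "anova_f"), rankings[0])
    ordered = sorted(rank_sum, key=lambda n: (rank_sum[n], anova.position(n), n))
    return FeatureRanking(ordered=[(n, float(rank_sum[n])) for n in ordered], source="VOTE")


def one_vs_rest_labels(labels: Sequence, quadrant: QuadrantLabel) -> list[str]:
    """Collapse quadrant labels into a binary target for one quadrant."""
    return [
        "positive" if (lab == quadrant or lab == quadrant.value) else "rest"
        for lab in labels
    ]


def rank_features(table: FeatureTable, target: QuadrantLabel | str = "4class", seed: int = 0) -> FeatureRanking:
    """Run the three tests and the vote for one classification target.

    ``target`` is ``"4class"`` for the multiclass problem or a quadrant for
    its one-vs-rest binary problem.
    """
    if isinstance(target, str) and target.lower() in ("4class", "4-class", "multiclass"):
        labels = None
    else:
        quad = target if isinstance(target, QuadrantLabel) else QuadrantLabel(str(target).capitalize())
        labels = one_vs_rest_labels(table.labels, quad)
    rankings = [
        rank_chi2(table, labels),
        rank_anova_f(table, labels),
        rank_mutual_info(table, labels, seed=seed),
    ]
    return vote(rankings)
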