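"""Classifier building, tuning, evaluation and thresholded prediction.

Two architectures are compared for recognising the emotional quadrant of
a feature vector: a single 4-class model, and four one-vs-rest binary
models (one per quadrant).  Five algorithm families are searched — KNN,
random forest, multi-layer perceptron, linear SVC and gradient boosting —
over random hyperparameter draws crossed with feature-count prefixes
{5, 8, 10, 12, 15} of a relevance ranking, scored by mean F1 under
repeated stratified 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import ParameterSampler, RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import LinearSVC

from .features import FEATURE_NAMES, FeatureTable, FeatureVector
from .quadrants import QUADRANT_ORDER, QuadrantLabel
from .selection import FeatureRanking, one_vs_rest_labels

__all__ = [
    "ALGORITHMS",
    "FOUR_CLASS",
    "ModelSpec",
    "EvaluationReport",
    "EmotionPrediction",
    "TrainedModel",
    "SearchSpace",
    "CVConfig",
    "train_and_tune",
    "evaluate",
    "select_best",
    "predict",
]

FOUR_CLASS = "4class"
POSITIVE, REST = "positive", "rest"

ALGORITHMS = ("KNN", "RF", "MLP", "LSVC", "GB")


class LogisticLSVC(BaseEstimator, ClassifierMixin):
    """Linear SVC that exposes probabilities via a logistic squash of its
    decision scores, so margin classifiers honour the probabilistic output
    contract shared by all five algorithm families."""

    def __init__(self, C: float = 1.0, class_weight=None, random_state: int | None = None):
        self.C = C
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        self._svc = LinearSVC(C=self.C, class_weight=self.class_weight, random_state=self.random_state)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict(self, X):
        return self._svc.predict(X)

    def predict_proba(self, X):
        scores = self._svc.decision_function(X)
        if scores.ndim == 1:
            p = expit(scores)
            return np.column_stack([1 - p, p])
        p = expit(scores)
        return p / p.sum(axis=1, keepdims=True)


def _make_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "MLP":
        return MLPClassifier(random_state=seed, max_iter=600, **params)
    if algorithm == "LSVC":
        return LogisticLSVC(random_state=seed, **params)
    if algorithm == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


#: Default randomized-search distributions per algorithm family.
DEFAULT_DISTRIBUTIONS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [1, 3, 5, 7, 9, 11, 15], "weights": ["uniform", "distance"]},
    "RF": {
        "n_estimators": [50, 100, 200],
        "max_depth": [None, 3, 5, 10],
        "max_features": ["sqrt", None],
        # the one-vs-rest subproblems are 25/75 imbalanced
        "class_weight": [None, "balanced"],
    },
    "MLP": {"hidden_layer_sizes": [(16,), (32,), (64,), (32, 16)], "alpha": [1e-4, 1e-3, 1e-2]},
    "LSVC": {"C": [0.01, 0.1, 1.0, 10.0, 100.0], "class_weight": [None, "balanced"]},
    "GB": {"n_estimators": [50, 100], "learning_rate": [0.05, 0.1, 0.2], "max_depth": [2, 3]},
}


@dataclass
class SearchSpace:
    """What the randomized model search explores."""

    algorithms: tuple = ALGORITHMS
    n_features_grid: tuple = (5, 8, 10, 12, 15)
    n_iter: int = 50
    distributions: Mapping[str, Mapping] = field(default_factory=lambda: DEFAULT_DISTRIBUTIONS)


@dataclass
class CVConfig:
    """Repeated stratified k-fold settings."""

    folds: int = 5
    repeats: int = 10


@dataclass
class ModelSpec:
    """A fully specified candidate model."""

    architecture: str  # FOUR_CLASS or the quadrant value for a binary model
    algorithm: str
    n_features: int
    hyperparameters: dict
    seed: int


@dataclass
class EvaluationReport:
    """Mean CV metrics (or held-out metrics) for one model."""

    accuracy: float
    f1: float
    precision: float
    recall: float
    architecture: str = FOUR_CLASS
    algorithm: str = ""
    n_features: int = 15
    cv: CVConfig | None = None


@dataclass
class EmotionPrediction:
    """Four (flag, probability) pairs in Happy, Sad, Aggressive, Relaxed
    order; a flag is set when its probability reaches the threshold."""

    flags: tuple
    probabilities: tuple
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.flags = tuple(bool(f) for f in self.flags)
        self.probabilities = tuple(float(p) for p in self.probabilities)
        if len(self.flags) != 4 or len(self.probabilities) != 4:
            raise ValueError("prediction must carry exactly four (flag, probability) pairs")

    @classmethod
    def from_probabilities(cls, probabilities, threshold: float = 0.5) -> "EmotionPrediction":
        """Derive the flag vector: a quadrant is flagged iff its
        probability reaches the classification threshold."""
        probs = tuple(float(p) for p in probabilities)
        return cls(flags=tuple(p >= threshold for p in probs), probabilities=probs, threshold=threshold)


@dataclass
class TrainedModel:
    """A fitted model bound to its feature subset and training target."""

    spec: ModelSpec
    estimator: object
    features: list
    report: EvaluationReport


def _target_vector(table: FeatureTable, architecture: str) -> np.ndarray:
    if architecture == FOUR_CLASS:
        return np.asarray([lab.value if isinstance(lab, QuadrantLabel) else str(lab) for lab in table.labels])
    quad = QuadrantLabel(architecture)
    return np.asarray(one_vs_rest_labels(table.labels, quad))


def _fold_metrics(y_true, y_pred, architecture: str) -> tuple[float, float, float, float]:
    if architecture == FOUR_CLASS:
        kw = dict(average="weighted", zero_division=0)
    else:
        kw = dict(pos_label=POSITIVE, zero_division=0)
    return (
        accuracy_score(y_true, y_pred),
        f1_score(y_true, y_pred, **kw),
        precision_score(y_true, y_pred, **kw),
        recall_score(y_true, y_pred, **kw),
    )


def _cv_evaluate(estimator, X: np.ndarray, y: np.ndarray, cv: CVConfig, seed: int, architecture: str) -> EvaluationReport:
    splitter = RepeatedStratifiedKFold(n_splits=cv.folds, n_repeats=cv.repeats, random_state=seed)
    metrics = []
    for train_idx, test_idx in splitter.split(X, y):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        metrics.append(_fold_metrics(y[test_idx], est.predict(X[test_idx]), architecture))
    acc, f1, prec, rec = np.mean(metrics, axis=0)
    return EvaluationReport(accuracy=float(acc), f1=float(f1), precision=float(prec), recall=float(rec), cv=cv)


def train_and_tune(
    table: FeatureTable,
    ranking: FeatureRanking,
    architecture: str = FOUR_CLASS,
    search: SearchSpace | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Search algorithms x hyperparameters x feature-count prefixes and
    return the best model by mean CV F1.

    The feature subsets tried are prefixes of ``ranking`` of the sizes in
    ``search.n_features_grid``.  When ``table`` is not yet normalized a
    min–max scaler is fitted inside each training fold (leakage-free);
    pass a normalized table to reproduce the whole-dataset-scaling
    convention.  All randomness flows from ``seed``.
    """
    search = search or SearchSpace()
    cv = cv or CVConfig()
    y = _target_vector(table, architecture)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv.folds:
        raise ValueError(f"smallest class has {counts.min()} rows; need >= {cv.folds} for stratified {cv.folds}-fold CV")
    missing = [n for n in table.data.columns if n not in ranking.names]
    if missing:
        raise ValueError(f"ranking does not cover table columns: {missing}")

    candidates: list[tuple[ModelSpec, EvaluationReport]] = []
    for algorithm in search.algorithms:
        dist = search.distributions.get(algorithm, {})
        n_conf = min(search.n_iter, int(np.prod([len(v) for v in dist.values()])) if dist else 1)
        for ni, n_features in enumerate(search.n_features_grid):
            n_features = min(n_features, len(ranking.names))
            feats = ranking.top(n_features)
            X = table.data[feats].values
            algo_tag = sum(ord(c) for c in algorithm)
            sampler_seed = (seed * 7919 + algo_tag * 131 + ni) % (2**31)
            for params in ParameterSampler(dist, n_iter=n_conf, random_state=sampler_seed):
                est = _make_estimator(algorithm, params, seed=seed % (2**31))
                if not table.normalized:
                    est = Pipeline([("scale", MinMaxScaler()), ("clf", est)])
                report = _cv_evaluate(est, X, y, cv, seed=seed % (2**31), architecture=architecture)
                report.architecture, report.algorithm, report.n_features = architecture, algorithm, n_features
                spec = ModelSpec(architecture, algorithm, n_features, dict(params), seed)
                candidates.append((spec, report))

    best_spec, best_report = min(
        candidates, key=lambda c: (-c[1].f1, -c[1].accuracy, c[0].algorithm)
    )
    feats = ranking.top(best_spec.n_features)
    final = _make_estimator(best_spec.algorithm, best_spec.hyperparameters, seed=seed % (2**31))
    if not table.normalized:
        final = Pipeline([("scale", MinMaxScaler()), ("clf", final)])
    final.fit(table.data[feats].values, y)
    return TrainedModel(spec=best_spec, estimator=final, features=feats, report=best_report)


def evaluate(predictions: Sequence, truth: Sequence, architecture: str = FOUR_CLASS) -> EvaluationReport:
    """Accuracy/F1/precision/recall for a prediction vector.

    Binary reports use the positive-class convention (precision and recall
    are 0 when undefined); 4-class reports weight per-class scores by
    class support.
    """
    if len(predictions) == 0 or len(predictions) != len(truth):
        raise ValueError("predictions and truth must be equal-length and non-empty")
    y_pred = np.asarray([p.value if isinstance(p, QuadrantLabel) else p for p in predictions])
    y_true = np.asarray([t.value if isinstance(t, QuadrantLabel) else t for t in truth])
    acc, f1, prec, rec = _fold_metrics(y_true, y_pred, architecture)
    return EvaluationReport(accuracy=float(acc), f1=float(f1), precision=float(prec), recall=float(rec),
                            architecture=architecture)


def select_best(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Pick the report with the highest F1 (ties: accuracy, then
    alphabetical algorithm name)."""
    if not reports:
        raise ValueError("no reports to select from")
    return min(reports, key=lambda r: (-r.f1, -r.accuracy, r.algorithm))


def _classes(estimator) -> list:
    classes = getattr(estimator, "classes_", None)
    if classes is None:  # pipeline
        classes = estimator[-1].classes_
    return list(classes)


def _positive_probability(model: TrainedModel, x: pd.Series) -> float:
    X = x[model.features].values.reshape(1, -1)
    proba = model.estimator.predict_proba(X)[0]
    return float(proba[_classes(model.estimator).index(POSITIVE)])


def predict(
    models: Mapping[QuadrantLabel, TrainedModel] | TrainedModel,
    x: FeatureVector | pd.Series,
    threshold: float = 0.5,
) -> EmotionPrediction:
    """Emit the four (flag, probability) pairs for one feature vector.

    ``models`` is either the mapping of four one-vs-rest binary models or
    a single 4-class model.  ``x`` must already be scaled with the
    training-time min–max transform; grossly out-of-range input raises.
    """
    x = x.to_series() if isinstance(x, FeatureVector) else x
    if (x < -1e-6).any() or (x > 1 + 1e-6).any():
        raise ValueError("feature vector is not min-max normalized; apply the training scaler first")
    if isinstance(models, TrainedModel):
        if models.spec.architecture != FOUR_CLASS:
            raise ValueError("a single model must be the 4-class architecture; pass binary models as a mapping")
        X = x[models.features].values.reshape(1, -1)
        proba = models.estimator.predict_proba(X)[0]
        classes = _classes(models.estimator)
        probs = tuple(float(proba[classes.index(q.value)]) for q in QUADRANT_ORDER)
    else:
        probs = tuple(_positive_probability(models[q], x) for q in QUADRANT_ORDER)
    return EmotionPrediction.from_probabilities(probs, threshold=threshold)
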