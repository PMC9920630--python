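"""End-to-end orchestration: offline training pipeline and the streaming
recognition loop.

The streaming loop mirrors the mobile application's data path: every 30 s
of wearable data is conditioned, summarised into the 15-feature vector
with the training-time min–max transform, and classified into the four
quadrant (flag, probability) pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .device_io import (
    LabeledSegment,
    RawSession,
    ValidationRules,
    segment_session,
    validate_session,
    write_segments,
)
from .features import ExtractionConfig, FeatureTable, build_feature_table, extract_features, normalize
from .models import (
    FOUR_CLASS,
    CVConfig,
    EmotionPrediction,
    SearchSpace,
    TrainedModel,
    predict,
    train_and_tune,
)
from .quadrants import QUADRANT_ORDER, QuadrantLabel
from .selection import rank_features
from .synthetic import ExperimentSpec, generate_experiment

__all__ = ["WindowConfig", "PipelineConfig", "PipelineArtifacts", "run_windowed_recognition", "run_training_pipeline"]


@dataclass(frozen=True)
class WindowConfig:
    """Tumbling-window settings for the streaming loop."""

    window_length: float = 30.0
    step: float = 30.0

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.step <= 0:
            raise ValueError("window_length and step must be positive")


def run_windowed_recognition(
    stream: RawSession,
    models,
    scaler_table: FeatureTable,
    config: WindowConfig | None = None,
    extraction: ExtractionConfig | None = None,
    threshold: float = 0.5,
) -> list[tuple[float, EmotionPrediction]]:
    """Classify each complete window of a raw stream.

    ``models`` is the mapping of four binary models (or one 4-class
    model); ``scaler_table`` the normalized training table carrying the
    fitted min–max extrema.  Returns ``(window_start_s, prediction)``
    pairs; a trailing partial window is dropped, and a stream shorter than
    one window yields an empty list with a warning.
    """
    config = config or WindowConfig()
    extraction = extraction or ExtractionConfig()
    t_rel = (stream.timestamps_ms - stream.timestamps_ms[0]) / 1000.0
    # span covered by the stream: last sample time plus one sample period
    duration = float(t_rel[-1]) + 1.0 / stream.nominal_rate if len(stream) else 0.0
    out = []
    start = 0.0
    while start + config.window_length <= duration + 1e-9:
        mask = (t_rel >= start) & (t_rel < start + config.window_length)
        window = RawSession(
            stream.timestamps_ms[mask],
            stream.resistance_ohm[mask],
            session_id=f"{stream.session_id}_w{int(start)}",
            nominal_rate=stream.nominal_rate,
        )
        fv = extract_features(window, extraction)
        x = scaler_table.transform(fv)
        out.append((start, predict(models, x, threshold=threshold)))
        start += config.step
    if not out:
        warnings.warn("stream shorter than one window; no predictions emitted")
    return out


@dataclass
class PipelineConfig:
    """One self-contained training run, from corpus to trained models."""

    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    profiles: dict | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    rules: ValidationRules = field(default_factory=ValidationRules)
    search: SearchSpace = field(default_factory=SearchSpace)
    cv: CVConfig = field(default_factory=CVConfig)
    architectures: tuple = (FOUR_CLASS,) + tuple(q.value for q in QUADRANT_ORDER)
    seed: int = 0
    out_dir: Path | None = None


@dataclass
class PipelineArtifacts:
    corpus: object
    segments: list
    features: FeatureTable
    normalized: FeatureTable
    rankings: dict
    models: dict  # architecture -> TrainedModel
    manifest: dict


def run_training_pipeline(config: PipelineConfig) -> PipelineArtifacts:
    """Run generation → validation → segmentation → features → selection →
    model search, collecting a manifest of counts and seeds at every stage.

    When ``config.out_dir`` is set the intermediate artifacts (segment
    files, feature CSV, ranking CSVs, manifest JSON) are written there.
    """
    corpus = generate_experiment(config.experiment, config.profiles)
    valid_sessions = []
    for session in corpus.sessions:
        if validate_session(session, config.experiment.protocol, config.rules):
            valid_sessions.append(session)
    segments: list[LabeledSegment] = []
    for session in valid_sessions:
        segments.extend(segment_session(session, config.experiment.protocol))
    if not segments:
        raise RuntimeError("training pipeline aborted at segmentation: no valid sessions in corpus")

    table = build_feature_table(segments, config.extraction)
    normalized = normalize(table)

    rankings = {arch: rank_features(normalized, target=arch, seed=config.seed) for arch in config.architectures}
    models = {
        arch: train_and_tune(
            normalized, rankings[arch], architecture=arch, search=config.search, cv=config.cv, seed=config.seed
        )
        for arch in config.architectures
    }

    per_quadrant = {
        q.value: int(sum(1 for s in segments if s.label == q)) for q in QUADRANT_ORDER
    }
    manifest = {
        "seed": config.seed,
        "n_sessions": len(corpus.sessions),
        "n_valid_sessions": len(valid_sessions),
        "n_segments": len(segments),
        "segments_per_quadrant": per_quadrant,
        "architectures": list(config.architectures),
        "selected": {
            arch: {
                "algorithm": m.spec.algorithm,
                "n_features": m.spec.n_features,
                "f1": m.report.f1,
                "accuracy": m.report.accuracy,
            }
            for arch, m in models.items()
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_segments(segments, out / "segments")
        feat = table.data.copy()
        feat["label"] = [lab.value for lab in table.labels]
        feat.to_csv(out / "features.csv", index=False)
        for arch, ranking in rankings.items():
            pd.DataFrame(ranking.ordered, columns=["feature", "rank_sum"]).to_csv(
                out / f"ranking_{arch}.csv", index_label="rank"
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineArtifacts(
        corpus=corpus,
        segments=segments,
        features=table,
        normalized=normalized,
        rankings=rankings,
        models=models,
        manifest=manifest,
    )
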