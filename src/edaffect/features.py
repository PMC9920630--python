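"""Per-segment feature extraction and min–max normalization.

Fifteen descriptors summarise each labeled conductance segment: nine
statistical features computed on the filtered trace (Mean, Median, Std,
Max, Min, Kurtosis, Skewness, AUC per second, median Welch PSD) and six
event-related features computed from the detected SCR peaks and offsets
(mean/max peak amplitude, mean/max offset amplitude, peaks and offsets
per second).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.signal import welch
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .device_io import LabeledSegment
from .preprocessing import EDASignal, preprocess
from .quadrants import QuadrantLabel
from .scr import DetectionParams, EventKind, SCREvent, decompose, detect_events

__all__ = [
    "FEATURE_NAMES",
    "STATISTICAL_FEATURES",
    "EVENT_FEATURES",
    "FeatureVector",
    "FeatureTable",
    "ExtractionConfig",
    "statistical_features",
    "event_features",
    "extract_features",
    "build_feature_table",
    "normalize",
]

STATISTICAL_FEATURES = ("Mean", "Median", "Std", "Max", "Min", "Kurtosis", "Skewness", "AUC", "PSD")
EVENT_FEATURES = ("MeanPA", "MaxPA", "MeanOA", "MaxOA", "PPS", "OPS")
FEATURE_NAMES = STATISTICAL_FEATURES + EVENT_FEATURES


@dataclass
class FeatureVector:
    """The 15 descriptors of one labeled segment."""

    Mean: float = np.nan
    Median: float = np.nan
    Std: float = np.nan
    Max: float = np.nan
    Min: float = np.nan
    Kurtosis: float = np.nan
    Skewness: float = np.nan
    AUC: float = np.nan
    PSD: float = np.nan
    MeanPA: float = 0.0
    MaxPA: float = 0.0
    MeanOA: float = 0.0
    MaxOA: float = 0.0
    PPS: float = 0.0
    OPS: float = 0.0

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in dataclass_fields(self)})


@dataclass
class FeatureTable:
    """Feature matrix plus quadrant labels for a corpus of segments.

    ``data`` has exactly the 15 feature columns; ``labels`` is aligned
    row-wise.  After :func:`normalize`, ``feature_min``/``feature_max``
    hold the fitted per-column extrema so future rows (e.g. streaming
    windows) can be transformed consistently.
    """

    data: pd.DataFrame
    labels: pd.Series
    normalized: bool = False
    feature_min: pd.Series | None = field(default=None, repr=False)
    feature_max: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(FEATURE_NAMES):
            self.data = self.data.loc[:, list(FEATURE_NAMES)]
        if len(self.data) != len(self.labels):
            raise ValueError("row/label counts differ")

    def __len__(self) -> int:
        return len(self.data)

    def transform(self, row: FeatureVector | pd.Series) -> pd.Series:
        """Apply the fitted min–max transform to a new feature vector."""
        if not self.normalized or self.feature_min is None:
            raise ValueError("table is not normalized; no fitted transform to apply")
        values = row.to_series() if isinstance(row, FeatureVector) else row
        span = (self.feature_max - self.feature_min).replace(0.0, np.inf)
        return ((values - self.feature_min) / span).clip(0.0, 1.0)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the per-segment extraction chain."""

    native_rate: float | None = None
    target_rate: float = 2.0
    median_window: int = 5
    tonic_window: float = 10.0
    detection: DetectionParams = DetectionParams()
    amplitude_units: str = "microsiemens"


def statistical_features(signal: EDASignal) -> FeatureVector:
    """Compute the nine statistical descriptors of a conductance trace.

    Std is the population standard deviation; Kurtosis is excess (Fisher)
    kurtosis and Skewness the standardized third moment, both defined as 0
    for a zero-variance trace; AUC is the trapezoidal integral divided by
    the trace duration; PSD is the median of the Welch power-spectral-
    density estimate (64-sample segments, 50% overlap).
    """
    v = signal.values
    if v.size < 2:
        raise ValueError("need at least 2 samples for statistical features")
    std = float(np.std(v))
    if std == 0.0:
        skewness = kurt = 0.0
    else:
        skewness = float(_skew(v))
        kurt = float(_kurtosis(v, fisher=True))
    duration = signal.duration_s
    auc = float(trapezoid(v, dx=1.0 / signal.rate) / duration) if duration > 0 else float(v.mean())
    nperseg = min(64, v.size)
    _, psd = welch(v, fs=signal.rate, nperseg=nperseg, noverlap=nperseg // 2)
    return FeatureVector(
        Mean=float(np.mean(v)),
        Median=float(np.median(v)),
        Std=std,
        Max=float(np.max(v)),
        Min=float(np.min(v)),
        Kurtosis=kurt,
        Skewness=skewness,
        AUC=auc,
        PSD=float(np.median(psd)),
    )


def event_features(
    events: Sequence[SCREvent], window_duration: float, amplitude_units: str = "microsiemens"
) -> FeatureVector:
    """Summarise detected SCR events over a window of known duration.

    Amplitude summaries default to 0 when no event of the respective kind
    occurred; PPS/OPS are event counts divided by the window duration in
    seconds.  ``amplitude_units="seconds"`` switches MeanPA/MaxPA/MeanOA/
    MaxOA from the phasic change in µS to the event duration in seconds —
    an alternative reading of what an event's "amplitude" summarises.
    """
    if window_duration <= 0:
        raise ValueError("window_duration must be positive")
    if amplitude_units not in ("microsiemens", "seconds"):
        raise ValueError("amplitude_units must be 'microsiemens' or 'seconds'")
    size = (lambda e: e.duration) if amplitude_units == "seconds" else (lambda e: e.amplitude)
    peak_amp = [size(e) for e in events if e.kind == EventKind.PEAK]
    off_amp = [size(e) for e in events if e.kind == EventKind.OFFSET]
    return FeatureVector(
        MeanPA=float(np.mean(peak_amp)) if peak_amp else 0.0,
        MaxPA=float(np.max(peak_amp)) if peak_amp else 0.0,
        MeanOA=float(np.mean(off_amp)) if off_amp else 0.0,
        MaxOA=float(np.max(off_amp)) if off_amp else 0.0,
        PPS=len(peak_amp) / window_duration,
        OPS=len(off_amp) / window_duration,
    )


def extract_features(segment, config: ExtractionConfig | None = None) -> FeatureVector:
    """Run the full extraction chain on one segment.

    Conditioning (convert → downsample → median filter) feeds the
    statistical features directly and, through tonic–phasic decomposition
    and SCR detection, the event-related features.  Deterministic for a
    fixed config.
    """
    config = config or ExtractionConfig()
    if isinstance(segment, EDASignal):
        eda = segment
    else:
        eda = preprocess(
            segment,
            native_rate=config.native_rate,
            target_rate=config.target_rate,
            median_window=config.median_window,
        )
    stat = statistical_features(eda)
    dec = decompose(eda, tonic_window=config.tonic_window)
    events = detect_events(dec, config.detection)
    # Window duration for the per-second rates is the segment duration.
    ev = event_features(
        events,
        window_duration=max(eda.duration_s, 1.0 / eda.rate),
        amplitude_units=config.amplitude_units,
    )
    for name in EVENT_FEATURES:
        setattr(stat, name, getattr(ev, name))
    return stat


def build_feature_table(segments: Sequence[LabeledSegment], config: ExtractionConfig | None = None) -> FeatureTable:
    """Extract features for every segment and assemble the labeled table."""
    rows = [extract_features(seg, config).to_series() for seg in segments]
    labels = pd.Series([seg.label for seg in segments], dtype=object)
    data = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureTable(data=data, labels=labels.reset_index(drop=True))


def normalize(table: FeatureTable, fit_rows: Sequence[int] | None = None) -> FeatureTable:
    """Min–max scale every column to [0, 1].

    Column extrema are fitted on ``fit_rows`` (default: all rows — the
    whole-dataset convention) and retained on the returned table for
    transforming future rows.  A constant column maps to all zeros.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty table")
    fit = table.data.iloc[list(fit_rows)] if fit_rows is not None else table.data
    cmin, cmax = fit.min(axis=0), fit.max(axis=0)
    span = (cmax - cmin).replace(0.0, np.inf)  # constant column -> all zeros
    data = ((table.data - cmin) / span).clip(lower=0.0, upper=1.0)
    return FeatureTable(
        data=data,
        labels=table.labels.copy(),
        normalized=True,
        feature_min=cmin,
        feature_max=cmax,
    )
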