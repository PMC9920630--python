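"""Signal conditioning: GSR→EDA conversion, 2 Hz downsampling, median filter.

These are the first three stages of the feature-extraction chain.  Skin
resistance (ohms) is converted to conductance (microsiemens) by the
physical reciprocal relation, resampled onto a uniform grid, reduced to
two samples per second by anti-aliasing block averaging, and cleaned of
motion artifacts with a median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .device_io import LabeledSegment, RawSession

__all__ = ["EDASignal", "gsr_to_eda", "downsample", "remove_artifacts", "preprocess"]


@dataclass
class EDASignal:
    """A uniformly sampled skin-conductance trace.

    ``values`` are in microsiemens, ``rate`` in Hz, ``start_time`` in
    seconds relative to the session clock.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("EDASignal needs a non-empty 1-D value array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("conductance values must be finite and non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate


def gsr_to_eda(source: RawSession | LabeledSegment, rate: float | None = None) -> EDASignal:
    """Convert a raw resistance trace to conductance in microsiemens.

    conductance(µS) = 1e6 / resistance(Ω).  Irregular device timestamps are
    resampled onto a uniform grid at ``rate`` (default: the session's
    nominal acquisition rate) by linear interpolation.
    """
    session = source.session if isinstance(source, LabeledSegment) else source
    if len(session) == 0:
        raise ValueError("empty session")
    if np.any(session.resistance_ohm <= 0):
        raise ValueError("resistance must be strictly positive")
    rate = rate or session.nominal_rate
    cond = 1e6 / session.resistance_ohm
    t = (session.timestamps_ms - session.timestamps_ms[0]) / 1000.0
    n = int(np.floor(t[-1] * rate)) + 1
    grid = np.arange(n) / rate
    values = np.interp(grid, t, cond)
    return EDASignal(values, rate=rate)


def downsample(signal: EDASignal, target_rate: float = 2.0) -> EDASignal:
    """Reduce the sample rate by block averaging (default 2 Hz).

    Each output sample is the mean of its source block, which both
    decimates and low-pass filters the trace.  If the input rate is not an
    integer multiple of the target the signal is first linearly resampled
    onto the nearest integer-multiple grid.  Raises on an upsampling
    request.
    """
    if target_rate > signal.rate:
        raise ValueError(f"cannot upsample from {signal.rate} Hz to {target_rate} Hz")
    if np.isclose(signal.rate, target_rate):
        return EDASignal(signal.values.copy(), rate=target_rate, start_time=signal.start_time)
    factor = signal.rate / target_rate
    values = signal.values
    if not np.isclose(factor, round(factor)):
        factor = max(int(np.ceil(factor)), 1)
        inter_rate = target_rate * factor
        grid = np.arange(int(np.floor(signal.duration_s * inter_rate)) + 1) / inter_rate
        values = np.interp(grid, signal.times - signal.start_time, signal.values)
    factor = int(round(factor))
    n_blocks = values.size // factor
    if n_blocks == 0:
        raise ValueError("signal shorter than one downsampling block")
    blocks = values[: n_blocks * factor].reshape(n_blocks, factor)
    return EDASignal(blocks.mean(axis=1), rate=target_rate, start_time=signal.start_time)


def remove_artifacts(signal: EDASignal, window: int = 5) -> EDASignal:
    """Median-filter the trace to suppress motion spikes.

    ``window`` is an odd sample count (default 5, i.e. 2.5 s at 2 Hz);
    edges use reflected padding, and length and rate are unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 3")
    filtered = median_filter(signal.values, size=window, mode="reflect")
    return EDASignal(filtered, rate=signal.rate, start_time=signal.start_time)


def preprocess(
    source: RawSession | LabeledSegment,
    native_rate: float | None = None,
    target_rate: float = 2.0,
    median_window: int = 5,
) -> EDASignal:
    """Full conditioning chain: convert, downsample, de-artifact."""
    eda = gsr_to_eda(source, rate=native_rate)
    eda = downsample(eda, target_rate=target_rate)
    return remove_artifacts(eda, window=median_window)
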