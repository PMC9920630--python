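"""Tonic–phasic decomposition and skin-conductance-response detection.

The conductance trace is split into a slow tonic level (skin conductance
level) and a fast phasic remainder (stimulus-locked responses).  A
physiologically relevant change — an SCR peak or offset — is a maximal run
of consecutive same-sign inter-sample slopes of at least 0.01 µS/s that
lasts at least 3 s.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .preprocessing import EDASignal

__all__ = ["PhasicDecomposition", "DetectionParams", "EventKind", "SCREvent", "decompose", "detect_events"]


@dataclass
class PhasicDecomposition:
    """Additive split of a conductance trace: ``tonic + phasic == input``."""

    tonic: np.ndarray
    phasic: np.ndarray
    rate: float


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds defining a physiologically relevant phasic change:
    an absolute slope of at least ``slope_threshold`` µS/s sustained for at
    least ``min_duration`` seconds."""

    slope_threshold: float = 0.01
    min_duration: float = 3.0

    def __post_init__(self) -> None:
        if self.slope_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("detection thresholds must be positive")


class EventKind(str, enum.Enum):
    PEAK = "PEAK"
    OFFSET = "OFFSET"


@dataclass
class SCREvent:
    """One detected phasic excursion.

    ``start_index``/``end_index`` are the sample indices of the run's first
    and last sample; ``duration = (end_index - start_index) / rate`` is the
    time between those endpoints, and ``amplitude`` the absolute phasic
    change across the run, in µS.
    """

    kind: EventKind
    start_index: int
    end_index: int
    duration: float
    amplitude: float

    def start_s(self, rate: float) -> float:
        return self.start_index / rate

    def end_s(self, rate: float) -> float:
        return self.end_index / rate


def decompose(signal: EDASignal, tonic_window: float = 10.0) -> PhasicDecomposition:
    """Split a trace into tonic and phasic components.

    The tonic component is a centred moving average over ``tonic_window``
    seconds (reflected padding at the edges) — a transparent linear
    smoother that keeps the decomposition exactly reconstructive; the
    phasic component is the residual.
    """
    n_window = int(round(tonic_window * signal.rate))
    if n_window % 2 == 0:
        n_window += 1  # keep the average centred (no half-sample shift)
    if len(signal) <= n_window:
        raise ValueError(
            f"signal of {len(signal)} samples is too short for a {tonic_window} s tonic window at {signal.rate} Hz"
        )
    tonic = uniform_filter1d(signal.values, size=max(n_window, 1), mode="reflect")
    phasic = signal.values - tonic
    return PhasicDecomposition(tonic=tonic, phasic=phasic, rate=signal.rate)


def detect_events(dec: PhasicDecomposition, params: DetectionParams | None = None) -> list[SCREvent]:
    """Find SCR peaks and offsets in the phasic component.

    Scans first differences of the phasic trace for maximal runs of
    consecutive slopes that all exceed ``slope_threshold`` in magnitude
    with a constant sign; runs sustained for at least ``min_duration`` are
    reported as PEAK (rising) or OFFSET (falling) events, time-ordered and
    non-overlapping.
    """
    params = params or DetectionParams()
    phasic = np.asarray(dec.phasic, dtype=float)
    if phasic.size < 2:
        return []
    slopes = np.diff(phasic) * dec.rate
    signs = np.where(slopes >= params.slope_threshold, 1, np.where(slopes <= -params.slope_threshold, -1, 0))

    events: list[SCREvent] = []
    min_slopes = params.min_duration * dec.rate  # run length in slope count
    i = 0
    n = signs.size
    while i < n:
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == s:
            j += 1
        k = j - i + 1  # number of slopes in the run; spans samples i..j+1
        duration = k / dec.rate
        if k >= min_slopes - 1e-9:
            events.append(
                SCREvent(
                    kind=EventKind.PEAK if s > 0 else EventKind.OFFSET,
                    start_index=i,
                    end_index=j + 1,
                    duration=duration,
                    amplitude=float(abs(phasic[j + 1] - phasic[i])),
                )
            )
        i = j + 1
    return events
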