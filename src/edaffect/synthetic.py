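"""Synthetic listening-experiment generator.

No public dataset accompanies the wearable study this package models, so
this module synthesises raw device logs with quadrant-conditioned
electrodermal structure: a slowly drifting tonic level, skin-conductance
responses (linear rise, exponential decay) arriving as a Poisson process
whose rate and amplitude follow the arousal axis, and additive sensor
noise.  A full experiment run emulates 32 one-session participants on the
nine-song protocol, with a configurable fraction of sessions corrupted so
the validation stage has something to discard.

Electrodermal dynamics here are driven by arousal (SCR rate and
amplitude); valence separability is injected through mild tonic-baseline
shifts as a modelling convenience, not a physiological claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .device_io import ProtocolSpec, RawSession, ValidationRules, default_protocol, validate_session
from .quadrants import RELAX, QuadrantLabel
from .scr import DetectionParams

__all__ = [
    "QuadrantProfile",
    "ExperimentSpec",
    "ExperimentCorpus",
    "GroundTruthEvent",
    "default_profiles",
    "contrast_profiles",
    "generate_segment",
    "generate_experiment",
]

CORRUPTION_MODES = ("truncate", "scramble_time", "out_of_range", "gap")


@dataclass(frozen=True)
class QuadrantProfile:
    """Electrodermal dynamics of one emotional condition.

    Parameters
    ----------
    tonic_baseline
        Mean skin conductance level, µS.
    tonic_drift_sd
        Random-walk scale of the tonic level, µS per sqrt(second).
    scr_rate
        SCR arrival rate, events/minute (Poisson).
    scr_amplitude_median, scr_amplitude_sigma
        Log-normal SCR amplitude: median in µS and log-scale sigma.
    scr_rise, scr_decay
        Kernel shape: linear rise time and exponential decay constant, s.
    noise_sd
        Additive Gaussian sensor noise, µS per sample.
    """

    tonic_baseline: float
    tonic_drift_sd: float = 0.005
    scr_rate: float = 2.0
    scr_amplitude_median: float = 0.2
    scr_amplitude_sigma: float = 0.25
    scr_rise: float = 3.5
    scr_decay: float = 4.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("tonic_baseline", "scr_rate", "scr_amplitude_median", "scr_rise", "scr_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def check_detectable(self, params: DetectionParams | None = None) -> None:
        """Assert the median injected rise is comfortably detectable:
        rise slope >= 3x the slope threshold and rise time >= the minimum
        duration."""
        params = params or DetectionParams()
        if self.scr_rate == 0:
            return
        slope = self.scr_amplitude_median / self.scr_rise
        if slope < 3 * params.slope_threshold - 1e-12:
            raise ValueError(
                f"median rise slope {slope:.4f} µS/s is below 3x the detection threshold "
                f"({3 * params.slope_threshold:.4f} µS/s)"
            )
        if self.scr_rise < params.min_duration:
            raise ValueError(f"rise time {self.scr_rise} s is below the minimum event duration {params.min_duration} s")


def default_profiles() -> dict:
    """Per-condition profiles for the four quadrants plus the relaxation
    song.

    High-arousal quadrants (Happy, Aggressive) respond often and strongly
    (6 SCR/min, 0.3 µS median); low-arousal ones rarely and weakly
    (1.5/min, 0.1 µS).  Baselines differ mildly with valence so all four
    quadrants remain distinguishable.
    """
    # Rise times exceed the 3 s detection rule by enough margin to survive
    # the ~0.5 s run erosion introduced by the 2.5 s median filter.
    high = dict(scr_rate=6.0, scr_amplitude_median=0.3, scr_rise=4.0)
    low = dict(scr_rate=1.5, scr_amplitude_median=0.1, scr_rise=3.3)
    return {
        QuadrantLabel.HAPPY: QuadrantProfile(tonic_baseline=6.0, **high),
        QuadrantLabel.AGGRESSIVE: QuadrantProfile(tonic_baseline=10.0, **high),
        QuadrantLabel.SAD: QuadrantProfile(tonic_baseline=2.0, **low),
        QuadrantLabel.RELAXED: QuadrantProfile(tonic_baseline=4.0, **low),
        RELAX: QuadrantProfile(tonic_baseline=3.0, scr_rate=1.0, scr_amplitude_median=0.1, scr_rise=3.3),
    }


def contrast_profiles(strength: float = 0.3) -> dict:
    """A graded-difficulty profile family for architecture experiments.

    Unlike :func:`default_profiles` (where the arousal axis dominates and
    corpora are easily separable), here each quadrant departs from a
    common physiology along its own electrodermal axis — Happy by SCR
    rate, Aggressive by SCR amplitude, Sad by tonic level, Relaxed by
    tonic variability — so that the discriminative features genuinely
    differ per quadrant.  ``strength`` in (0, 1] scales all four
    contrasts: near 1 the classes are well separated, near 0 they
    overlap heavily and recognition degrades toward chance.
    """
    if not 0 < strength <= 1:
        raise ValueError("strength must be in (0, 1]")
    common = dict(
        tonic_baseline=5.0,
        tonic_drift_sd=0.02,
        scr_rate=2.5,
        scr_amplitude_median=0.15,
        scr_amplitude_sigma=0.4,
        scr_rise=4.0,
        scr_decay=4.0,
        noise_sd=0.01,
    )

    def mk(**over):
        merged = dict(common)
        merged.update(over)
        return QuadrantProfile(**merged)

    return {
        QuadrantLabel.HAPPY: mk(scr_rate=2.5 + 5.5 * strength),
        QuadrantLabel.AGGRESSIVE: mk(scr_amplitude_median=0.15 + 0.35 * strength),
        QuadrantLabel.SAD: mk(tonic_baseline=5.0 - 2.0 * strength),
        QuadrantLabel.RELAXED: mk(tonic_drift_sd=0.02 + 0.06 * strength),
        RELAX: mk(),
    }


@dataclass
class GroundTruthEvent:
    """One injected SCR: onset of the rise, in seconds from chunk start."""

    onset_s: float
    amplitude: float

    @property
    def rise_interval(self) -> tuple[float, float]:  # pragma: no cover - convenience
        return (self.onset_s, self.onset_s)


@dataclass(frozen=True)
class ExperimentSpec:
    """The simulated listening study.

    Defaults emulate the reference protocol: 32 participants, 7 corrupted
    sessions, nine songs (one relaxation + two per quadrant) separated by
    15 s pauses, ~41 min per session.
    """

    n_participants: int = 32
    n_invalid: int = 7
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    native_rate: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invalid > self.n_participants:
            raise ValueError("n_invalid cannot exceed n_participants")


def _eda_chunk(profile: QuadrantProfile, duration: float, rate: float, rng: np.random.Generator):
    """Synthesize one conductance chunk; returns (values, ground_truth)."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    walk = np.cumsum(rng.normal(0.0, profile.tonic_drift_sd / math.sqrt(rate), size=n))
    eda = profile.tonic_baseline + walk
    events: list[GroundTruthEvent] = []
    n_events = rng.poisson(profile.scr_rate * duration / 60.0)
    onsets = np.sort(rng.uniform(0.0, max(duration - profile.scr_rise, 1e-6), size=n_events))
    for onset in onsets:
        amp = profile.scr_amplitude_median * math.exp(rng.normal(0.0, profile.scr_amplitude_sigma))
        rel = t - onset
        kernel = np.where(
            rel < 0,
            0.0,
            np.where(
                rel < profile.scr_rise,
                amp * rel / profile.scr_rise,
                amp * np.exp(-(rel - profile.scr_rise) / profile.scr_decay),
            ),
        )
        eda += kernel
        events.append(GroundTruthEvent(onset_s=float(onset), amplitude=float(amp)))
    if profile.noise_sd > 0:
        eda += rng.normal(0.0, profile.noise_sd, size=n)
    return np.clip(eda, 0.05, None), events


def _to_session(eda: np.ndarray, rate: float, session_id: str) -> RawSession:
    resistance = 1e6 / eda
    # Emulate the device's printed precision so log round-trips are exact.
    resistance = np.array([float(f"{r:.6g}") for r in resistance])
    timestamps = np.round(np.arange(eda.size) * 1000.0 / rate)
    return RawSession(timestamps, resistance, session_id=session_id, nominal_rate=rate)


def generate_segment(
    profile: QuadrantProfile,
    duration: float,
    rate: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> tuple[RawSession, list[GroundTruthEvent]]:
    """Generate one raw-format trace under a single condition.

    Returns the session fragment together with the injected ground-truth
    SCR onsets, so detector recovery can be scored.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eda, events = _eda_chunk(profile, duration, rate, rng)
    return _to_session(eda, rate, session_id=f"segment_{profile.tonic_baseline:g}uS"), events


def _corrupt(session: RawSession, mode: str, rng: np.random.Generator) -> RawSession:
    t = session.timestamps_ms.copy()
    r = session.resistance_ohm.copy()
    n = t.size
    if mode == "truncate":
        keep = n // 2
        t, r = t[:keep], r[:keep]
    elif mode == "scramble_time":
        i = int(rng.integers(n // 4, 3 * n // 4))
        t[i], t[i + 1] = t[i + 1], t[i]
    elif mode == "out_of_range":
        i = int(rng.integers(n // 4, 3 * n // 4))
        r[i : i + 10] = 5e3  # below any plausible skin resistance
    elif mode == "gap":
        i = int(rng.integers(n // 4, 3 * n // 4))
        width = int(10 * session.nominal_rate)  # 10 s hole
        t = np.delete(t, slice(i, i + width))
        r = np.delete(r, slice(i, i + width))
    else:  # pragma: no cover - guarded by CORRUPTION_MODES
        raise ValueError(f"unknown corruption mode {mode!r}")
    return RawSession(t, r, session_id=session.session_id, nominal_rate=session.nominal_rate)


@dataclass
class ExperimentCorpus:
    """Output of a simulated experiment: sessions plus ground truth."""

    sessions: list
    manifest: pd.DataFrame  # one row per (session, song slot)
    session_table: pd.DataFrame  # one row per session: session_id, valid, corruption


def generate_experiment(spec: ExperimentSpec, profiles: dict | None = None) -> ExperimentCorpus:
    """Simulate the full listening study.

    Every participant yields one session following the protocol schedule
    (pauses filled with relaxation-like activity); ``spec.n_invalid``
    sessions are corrupted, cycling through truncation, clock scramble,
    out-of-range bursts and acquisition gaps so each validation failure
    mode occurs.  A manifest records, per song slot, the quadrant label
    and the injected SCR onsets.  Pure function of (spec, profiles, seed).
    """
    profiles = profiles or default_profiles()
    missing = [q for q in list(QuadrantLabel) + [RELAX] if q not in profiles]
    if missing:
        raise ValueError(f"profiles missing conditions: {missing}")
    rng = np.random.default_rng(spec.seed)
    invalid_ids = set(rng.choice(spec.n_participants, size=spec.n_invalid, replace=False).tolist())

    sessions, manifest_rows, session_rows = [], [], []
    rate = spec.native_rate
    n_corrupted = 0
    for p in range(spec.n_participants):
        session_id = f"participant{p:02d}"
        chunks = []
        schedule = spec.protocol.schedule()
        pause = spec.protocol.pause_s
        for song_index, (label, start_s, end_s) in enumerate(schedule):
            eda, events = _eda_chunk(profiles[label], end_s - start_s, rate, rng)
            chunks.append(eda)
            manifest_rows.append(
                {
                    "session_id": session_id,
                    "song_index": song_index,
                    "label": label.value if isinstance(label, QuadrantLabel) else str(label),
                    "song_start_s": start_s,
                    "n_injected": len(events),
                    "event_onsets_s": ";".join(f"{e.onset_s:.3f}" for e in events),
                }
            )
            if pause > 0 and song_index < len(schedule) - 1:
                eda_pause, _ = _eda_chunk(profiles[RELAX], pause, rate, rng)
                chunks.append(eda_pause)
        eda_full = np.concatenate(chunks)
        session = _to_session(eda_full, rate, session_id)
        corruption = ""
        if p in invalid_ids:
            corruption = CORRUPTION_MODES[n_corrupted % len(CORRUPTION_MODES)]
            session = _corrupt(session, corruption, rng)
            n_corrupted += 1
        sessions.append(session)
        session_rows.append({"session_id": session_id, "corrupted": corruption, "valid": not corruption})

    session_table = pd.DataFrame(session_rows)
    manifest = pd.DataFrame(manifest_rows)
    return ExperimentCorpus(sessions=sessions, manifest=manifest, session_table=session_table)
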