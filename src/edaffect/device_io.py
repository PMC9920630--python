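"""Raw wearable log I/O, session validation and per-song segmentation.

The wearable stores one delimited text file per listening session: each
record is ``timestamp_ms,resistance_ohm`` (an optional single header line
is tolerated).  Sessions are validated against the experiment protocol
(coverage, monotone clock, plausible resistance, no acquisition gaps) and
then split into one labeled segment per song, with the introductory
relaxation song and the inter-song pauses discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .quadrants import RELAX, QuadrantLabel, coerce_label

__all__ = [
    "RawSample",
    "RawSession",
    "ProtocolSpec",
    "ValidationRules",
    "ValidationReport",
    "LabeledSegment",
    "read_raw_log",
    "write_raw_log",
    "validate_session",
    "segment_session",
    "write_segments",
    "default_protocol",
    "load_protocol",
]


class RawSample(NamedTuple):
    """One device record: milliseconds since session start, ohms."""

    timestamp: float
    resistance: float


@dataclass
class RawSession:
    """A timestamped skin-resistance trace downloaded from the device.

    Parameters
    ----------
    timestamps_ms
        Sample times in milliseconds since session start, strictly
        increasing for a healthy session.
    resistance_ohm
        Skin resistance readings in ohms (positive).
    session_id
        Opaque identifier, typically the source filename stem.
    nominal_rate
        The device acquisition rate in Hz.  The wearable's native rate is
        configurable; 8 Hz is used as the package default.
    """

    timestamps_ms: np.ndarray
    resistance_ohm: np.ndarray
    session_id: str = "session"
    nominal_rate: float = 8.0

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        if self.timestamps_ms.ndim != 1 or self.timestamps_ms.shape != self.resistance_ohm.shape:
            raise ValueError("timestamps and resistances must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.timestamps_ms.size

    @property
    def samples(self) -> Iterable[RawSample]:
        return (RawSample(t, r) for t, r in zip(self.timestamps_ms, self.resistance_ohm))

    @property
    def duration_s(self) -> float:
        """Span between first and last sample, in seconds."""
        if len(self) == 0:
            return 0.0
        return float(self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0

    @classmethod
    def from_samples(
        cls, samples: Sequence[RawSample | tuple], session_id: str = "session", nominal_rate: float = 8.0
    ) -> "RawSession":
        arr = np.asarray(samples, dtype=float).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1], session_id=session_id, nominal_rate=nominal_rate)


@dataclass(frozen=True)
class ProtocolSpec:
    """Schedule of a listening session.

    ``songs`` is the ordered list of ``(label, duration_s)`` slots, where
    label is a :class:`QuadrantLabel` or the :data:`~edaffect.quadrants.RELAX`
    sentinel.  ``pause_s`` seconds of silence separate consecutive songs so
    that the physiological response to one song does not bleed into the
    next.
    """

    songs: tuple = ()
    pause_s: float = 15.0
    relax_first: bool = True

    def __post_init__(self) -> None:
        if self.pause_s < 0:
            raise ValueError("pause_s must be >= 0")
        n_relax = sum(1 for label, _ in self.songs if label == RELAX)
        if self.relax_first and self.songs:
            if n_relax != 1 or self.songs[0][0] != RELAX:
                raise ValueError("relax_first protocol requires exactly one leading RELAX slot")

    @property
    def total_duration_s(self) -> float:
        """Full schedule length: songs plus the pauses between them."""
        if not self.songs:
            return 0.0
        song_time = sum(d for _, d in self.songs)
        return song_time + self.pause_s * (len(self.songs) - 1)

    def schedule(self) -> list[tuple[object, float, float]]:
        """Return ``(label, start_s, end_s)`` for every song slot."""
        out, t = [], 0.0
        for label, duration in self.songs:
            out.append((label, t, t + duration))
            t += duration + self.pause_s
        return out


def load_protocol(path) -> ProtocolSpec:
    """Read a session protocol from a YAML/JSON config file.

    Expected structure::

        pause_s: 15
        relax_first: true
        songs:
          - [Relax, 260]
          - [Happy, 260]
          ...
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    songs = []
    for label, duration in raw.get("songs", []):
        label = RELAX if str(label).lower() == RELAX.lower() else coerce_label(label)
        songs.append((label, float(duration)))
    return ProtocolSpec(
        songs=tuple(songs),
        pause_s=float(raw.get("pause_s", 15.0)),
        relax_first=bool(raw.get("relax_first", any(l == RELAX for l, _ in songs))),
    )


def default_protocol(song_duration_s: float = 260.0, pause_s: float = 15.0) -> ProtocolSpec:
    """The nine-song listening protocol: one relaxation song followed by
    two songs per quadrant, 15 s pauses, ~41 min in total.

    With the default 260 s songs the schedule lasts 9*260 + 8*15 = 2460 s
    (41 min exactly).
    """
    songs = [(RELAX, song_duration_s)]
    for quad in (QuadrantLabel.HAPPY, QuadrantLabel.SAD, QuadrantLabel.AGGRESSIVE, QuadrantLabel.RELAXED):
        songs.extend([(quad, song_duration_s), (quad, song_duration_s)])
    return ProtocolSpec(songs=tuple(songs), pause_s=pause_s, relax_first=True)


# --------------------------------------------------------------------------
# raw log dialect


def read_raw_log(path, session_id: str | None = None, nominal_rate: float = 8.0) -> RawSession:
    """Parse a raw device log into a :class:`RawSession`.

    The dialect is comma-separated ``timestamp_ms,resistance_ohm`` with an
    optional single header line.  Raises ``ValueError`` naming the line
    number on a malformed record and on an empty file.
    """
    path = Path(path)
    timestamps, resistances = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                t, r = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1:  # tolerated header line
                    continue
                raise ValueError(f"{path}: malformed record at line {lineno}: {line!r}")
            timestamps.append(t)
            resistances.append(r)
    if not timestamps:
        raise ValueError(f"{path}: empty raw log")
    order = np.argsort(timestamps, kind="stable")
    return RawSession(
        np.asarray(timestamps)[order],
        np.asarray(resistances)[order],
        session_id=session_id or path.stem,
        nominal_rate=nominal_rate,
    )


def write_raw_log(session: RawSession, path, header: bool = True) -> None:
    """Write a session in the raw log dialect (6 significant digits on
    resistance; integral timestamps printed as integers)."""
    if len(session) == 0:
        raise ValueError("refusing to write an empty session")
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("timestamp_ms,resistance_ohm\n")
        for t, r in zip(session.timestamps_ms, session.resistance_ohm):
            t_txt = f"{int(t)}" if float(t).is_integer() else f"{t:.6g}"
            fh.write(f"{t_txt},{r:.6g}\n")


# --------------------------------------------------------------------------
# validation

TRUNCATED = "TRUNCATED"
NONMONOTONE_TIME = "NONMONOTONE_TIME"
OUT_OF_RANGE = "OUT_OF_RANGE"
GAP = "GAP"


@dataclass(frozen=True)
class ValidationRules:
    """Operational definition of a usable session.

    A session must cover at least ``min_coverage`` of the protocol
    duration, keep a strictly increasing clock, stay inside a plausible
    skin-resistance range and contain no acquisition gap longer than
    ``max_gap_s``.
    """

    min_coverage: float = 0.90
    resistance_min_ohm: float = 1e4
    resistance_max_ohm: float = 1e7
    max_gap_s: float = 5.0


@dataclass
class ValidationReport:
    valid: bool
    reasons: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.valid


def validate_session(
    session: RawSession,
    protocol: ProtocolSpec,
    rules: ValidationRules | None = None,
) -> ValidationReport:
    """Check a session against the protocol; reports, never raises.

    Returns a :class:`ValidationReport` whose ``reasons`` list any of
    ``TRUNCATED``, ``NONMONOTONE_TIME``, ``OUT_OF_RANGE``, ``GAP``.
    """
    rules = rules or ValidationRules()
    reasons = []
    t = session.timestamps_ms
    r = session.resistance_ohm
    if len(session) == 0:
        return ValidationReport(False, [TRUNCATED])
    if protocol.total_duration_s > 0 and session.duration_s < rules.min_coverage * protocol.total_duration_s:
        reasons.append(TRUNCATED)
    if np.any(np.diff(t) <= 0):
        reasons.append(NONMONOTONE_TIME)
    if np.any((r < rules.resistance_min_ohm) | (r > rules.resistance_max_ohm)):
        reasons.append(OUT_OF_RANGE)
    dt = np.diff(t) / 1000.0
    if dt.size and np.max(dt) > rules.max_gap_s:
        reasons.append(GAP)
    return ValidationReport(not reasons, reasons)


# --------------------------------------------------------------------------
# segmentation


@dataclass
class LabeledSegment:
    """The sub-trace recorded while one quadrant-labeled song played.

    Timestamps are rebased so the segment starts at 0 ms.
    """

    label: QuadrantLabel
    session: RawSession
    source_session: str
    song_index: int

    @property
    def duration_s(self) -> float:
        return self.session.duration_s


def segment_session(session: RawSession, protocol: ProtocolSpec) -> list[LabeledSegment]:
    """Split a valid session into one labeled segment per non-relax song.

    Segments cover the half-open interval ``[song_start, song_end)`` on the
    schedule clock; the relaxation song and the inter-song pauses are
    discarded.  Raises ``ValueError`` if the trace ends before the schedule
    does.
    """
    if protocol.songs and session.duration_s < protocol.total_duration_s - 1.0 / max(session.nominal_rate, 1e-9):
        raise ValueError(
            f"session {session.session_id!r} ({session.duration_s:.1f} s) is shorter than "
            f"the protocol schedule ({protocol.total_duration_s:.1f} s)"
        )
    t0 = session.timestamps_ms[0] if len(session) else 0.0
    t_rel = session.timestamps_ms - t0
    segments = []
    for song_index, (label, start_s, end_s) in enumerate(protocol.schedule()):
        if label == RELAX:
            continue
        mask = (t_rel >= start_s * 1000.0) & (t_rel < end_s * 1000.0)
        sub = RawSession(
            t_rel[mask] - start_s * 1000.0,
            session.resistance_ohm[mask],
            session_id=f"{session.session_id}_song{song_index}",
            nominal_rate=session.nominal_rate,
        )
        segments.append(
            LabeledSegment(
                label=coerce_label(label),
                session=sub,
                source_session=session.session_id,
                song_index=song_index,
            )
        )
    return segments


def write_segments(segments: Sequence[LabeledSegment], out_dir) -> Path:
    """Write one raw-log file per segment plus a label manifest CSV.

    Returns the manifest path.  Manifest columns:
    ``segment_file,label,session_id,song_index``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "segments.csv"
    with open(manifest, "w") as fh:
        fh.write("segment_file,label,session_id,song_index\n")
        for seg in segments:
            fname = f"{seg.source_session}_song{seg.song_index}.csv"
            write_raw_log(seg.session, out_dir / fname)
            fh.write(f"{fname},{seg.label.value},{seg.source_session},{seg.song_index}\n")
    return manifest
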