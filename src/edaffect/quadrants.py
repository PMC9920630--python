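"""Russell circumplex quadrants.

Emotions are located in a two-dimensional valence x arousal space; the
four quadrants used throughout the package are Happy (+valence, +arousal),
Aggressive (-, +), Sad (-, -) and Relaxed (+, -).
"""

from __future__ import annotations

import enum


class QuadrantLabel(str, enum.Enum):
    """The four emotional quadrants of the circumplex model."""

    HAPPY = "Happy"
    SAD = "Sad"
    AGGRESSIVE = "Aggressive"
    RELAXED = "Relaxed"

    @property
    def valence(self) -> int:
        """Sign of the pleasure/displeasure axis (+1 or -1)."""
        return +1 if self in (QuadrantLabel.HAPPY, QuadrantLabel.RELAXED) else -1

    @property
    def arousal(self) -> int:
        """Sign of the intensity axis (+1 or -1)."""
        return +1 if self in (QuadrantLabel.HAPPY, QuadrantLabel.AGGRESSIVE) else -1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Sentinel label for the introductory relaxation song in a session
#: protocol.  It marks a schedule slot, not an emotion class, and is
#: discarded during segmentation.
RELAX = "Relax"

#: Canonical prediction/output order used everywhere a 4-vector appears.
QUADRANT_ORDER = (
    QuadrantLabel.HAPPY,
    QuadrantLabel.SAD,
    QuadrantLabel.AGGRESSIVE,
    QuadrantLabel.RELAXED,
)


def coerce_label(value) -> QuadrantLabel:
    """Map a string or enum to a :class:`QuadrantLabel` (case-insensitive)."""
    if isinstance(value, QuadrantLabel):
        return value
    try:
        return QuadrantLabel(str(value).capitalize())
    except ValueError as exc:
        raise ValueError(f"unknown quadrant label: {value!r}") from exc
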