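"""Posture label vocabulary for the sitting-posture monitoring system.

Seven classification targets (one standing + six sitting categories) are
recognized by the garment. At acquisition time the leg-crossed class is
recorded as two sub-variants (left / right leg crossed); because the four
back-mounted capacitance channels barely distinguish them, both sub-variants
share a single classification code.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class Posture(IntEnum):
    """Classification label codes for the seven posture classes."""

    STANCE = 0
    UPRIGHT = 1
    BACK_BENT = 2
    LEG_CROSSED = 3
    FORWARD = 4
    BACKWARD = 5
    OTHER = 6

    @property
    def label_name(self) -> str:
        return self.name.lower()


#: Sitting postures (everything except standing). These are the labels that
#: keep the sedentary timer running and that the hazard tiers partition.
SITTING_POSTURES: frozenset[Posture] = frozenset(
    p for p in Posture if p is not Posture.STANCE
)

_NAME_TO_POSTURE = {p.name.lower(): p for p in Posture}

#: Acquisition-time sub-variant tags. Only the leg-crossed class has
#: non-trivial sub-variants.
SUB_VARIANTS = ("left_crossed", "right_crossed", "none")


def posture_from_name(name: str) -> Posture:
    """Resolve a posture name (case-insensitive) to its label.

    Raises ``ValueError`` naming the offending value for unknown names.
    """
    try:
        return _NAME_TO_POSTURE[str(name).lower()]
    except KeyError:
        raise ValueError(f"unknown posture name: {name!r}") from None


@dataclass(frozen=True)
class AcquiredPosture:
    """A posture as acquired in the protocol: label plus optional sub-variant.

    There are eight acquired types: stance, upright, back_bent,
    leg_crossed/left, leg_crossed/right, forward, backward, other.
    """

    label: Posture
    sub_variant: str = "none"

    def __post_init__(self) -> None:
        if self.sub_variant not in SUB_VARIANTS:
            raise ValueError(f"unknown sub_variant: {self.sub_variant!r}")
        if self.label is Posture.LEG_CROSSED:
            if self.sub_variant == "none":
                raise ValueError(
                    "leg_crossed is acquired as left_crossed or right_crossed"
                )
        elif self.sub_variant != "none":
            raise ValueError(
                f"sub_variant is only meaningful for leg_crossed, got "
                f"{self.label.label_name}/{self.sub_variant}"
            )

    @property
    def key(self) -> str:
        """Stable string key, e.g. ``"leg_crossed/left_crossed"``."""
        if self.sub_variant == "none":
            return self.label.label_name
        return f"{self.label.label_name}/{self.sub_variant}"


#: The eight acquired posture types, in protocol acquisition order.
ACQUIRED_TYPES: tuple[AcquiredPosture, ...] = (
    AcquiredPosture(Posture.STANCE),
    AcquiredPosture(Posture.UPRIGHT),
    AcquiredPosture(Posture.BACK_BENT),
    AcquiredPosture(Posture.LEG_CROSSED, "left_crossed"),
    AcquiredPosture(Posture.LEG_CROSSED, "right_crossed"),
    AcquiredPosture(Posture.FORWARD),
    AcquiredPosture(Posture.BACKWARD),
    AcquiredPosture(Posture.OTHER),
)

#: Channel column names for the four capacitance sensors.
CHANNELS = ("c1", "c2", "c3", "c4")
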