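"""Synthetic 4-channel capacitance-signal simulator.

Emulates the acquisition protocol of the textile-sensor garment: each
participant holds each of the eight acquired posture types for a fixed
duration while the controller samples the four capacitance channels at 2 Hz,
giving 60 frames per posture, 480 per participant and 9600 for the default
cohort of 20.

Signal model: the value of channel ``c`` in posture ``p`` for participant
``i`` is ``s_ic * mu[p, c] + eps`` where ``mu`` is a fixed per-posture
class-mean table, ``s_ic ~ Normal(1, participant_scale_sd)`` is a
participant- and channel-level gain factor standing in for height/weight and
sensor-placement differences, and ``eps ~ Normal(0, noise_sd * r_p)`` is
i.i.d. sensor noise with a per-posture relative factor ``r_p`` (postures
with more muscle movement are noisier).

The class-mean table is synthetic (no real capacitance values are
modelled); it is built so that channel C1 carries the largest between-class
spread, the six defined posture classes are separated by several noise SDs
on C1, and the left/right leg-crossed pair differs by less than one noise
SD on every channel — so the sub-variants are not reliably separable from
four channels alone. The catch-all "other" class is a mixture: its
signatures interleave *between* the defined postures' signatures along C1,
each mode lying closer to its neighbours than any two defined classes lie
to each other. This reflects that miscellaneous postures (tilting,
slouching variants) fill the signal space around the acquired set, and it
is what makes the class hard: recognising "other" requires carving several
narrow intervals out of the C1 axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .postures import ACQUIRED_TYPES, CHANNELS, Posture

#: Synthetic per-(acquired posture, channel) mean capacitance table,
#: arbitrary capacitance units. Provenance: synthetic (constraint-driven,
#: see module docstring); no physical capacitances are reproduced.
DEFAULT_CLASS_MEANS: dict[str, tuple[float, float, float, float]] = {
    "stance": (4.0, 10.0, 10.0, 10.0),
    "upright": (10.0, 10.0, 10.0, 10.0),
    "back_bent": (16.0, 13.0, 9.0, 10.0),
    "leg_crossed/left_crossed": (22.0, 11.5, 8.0, 12.5),
    "leg_crossed/right_crossed": (22.4, 11.0, 8.4, 12.5),
    "forward": (27.5, 9.0, 12.0, 9.5),
    "backward": (33.0, 14.0, 11.0, 11.0),
    "other": (24.7, 10.0, 10.3, 11.0),
}

#: Mixture modes for the catch-all "other" class (includes its class_means
#: entry): miscellaneous-posture signatures interleaved between the defined
#: classes along channel C1. Provenance: synthetic.
DEFAULT_OTHER_MODES: tuple[tuple[float, float, float, float], ...] = (
    (13.0, 11.8, 9.3, 10.2),
    (19.0, 12.5, 8.3, 11.5),
    (24.7, 10.0, 10.3, 11.0),
    (30.2, 11.3, 11.8, 10.0),
)

#: Per-posture relative noise factors (multiply ``noise_sd``): postures with
#: larger sustained muscle engagement show noisier capacitance traces.
DEFAULT_NOISE_SCALE: dict[str, float] = {
    "stance": 0.7,
    "upright": 0.8,
    "back_bent": 1.0,
    "leg_crossed/left_crossed": 1.2,
    "leg_crossed/right_crossed": 1.2,
    "forward": 1.2,
    "backward": 1.0,
    "other": 1.0,
}

FRAME_COLUMNS = ["t", "participant", "posture_code", "sub_variant", *CHANNELS]


class InvalidConfigError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


@dataclass
class SimConfig:
    """Full parameterization of the synthetic signal model and protocol.

    Parameters
    ----------
    n_participants : cohort size (default 20).
    sampling_rate : controller sampling frequency in Hz (default 2).
    duration_per_posture : seconds each posture is held (default 30).
    class_means : map acquired-posture key -> 4-vector of channel baselines
        (arbitrary capacitance units). The "other" entry is that class's
        principal mode; ``other_modes`` carries its full mixture.
    other_modes : mixture component means for the catch-all "other" class.
    noise_scale : per-posture relative noise factors (multiply noise_sd).
    participant_scale_sd : SD of the per-channel multiplicative participant
        gain factor (dimensionless; default 0.04).
    noise_sd : base SD of additive per-frame sensor noise (capacitance
        units).
    crossed_gap : maximum per-channel distance allowed between the left and
        right leg-crossed class means (capacitance units; <= noise_sd by
        default so the sub-variants stay indistinguishable).
    seed : base seed; participant ``i`` uses ``seed + i``.
    """

    n_participants: int = 20
    sampling_rate: float = 2.0
    duration_per_posture: float = 30.0
    class_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    other_modes: tuple[tuple[float, ...], ...] = DEFAULT_OTHER_MODES
    noise_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SCALE)
    )
    participant_scale_sd: float = 0.04
    noise_sd: float = 0.7
    crossed_gap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if self.sampling_rate <= 0 or self.duration_per_posture <= 0:
            raise InvalidConfigError("sampling rate and duration must be positive")
        if self.participant_scale_sd < 0 or self.noise_sd < 0 or self.crossed_gap < 0:
            raise InvalidConfigError("standard deviations must be non-negative")
        means = self.mean_matrix()
        if means.shape != (len(ACQUIRED_TYPES), 4):
            raise InvalidConfigError(
                "class_means must cover all 8 acquired posture types with 4 channels"
            )
        missing = {t.key for t in ACQUIRED_TYPES} - set(self.noise_scale)
        if missing or any(v < 0 for v in self.noise_scale.values()):
            raise InvalidConfigError(
                "noise_scale must give every acquired type a non-negative factor"
            )
        modes = np.asarray(self.other_modes, dtype=float)
        if modes.ndim != 2 or modes.shape[1] != 4 or len(modes) == 0:
            raise InvalidConfigError("other_modes must be a non-empty list of 4-vectors")
        means = np.vstack([means, modes])
        spread = means.max(axis=0) - means.min(axis=0)
        if not np.all(spread[0] > spread[1:]):
            raise InvalidConfigError(
                "channel c1 must carry the largest between-class spread"
            )
        left = np.asarray(self.class_means["leg_crossed/left_crossed"], float)
        right = np.asarray(self.class_means["leg_crossed/right_crossed"], float)
        if np.max(np.abs(left - right)) > self.crossed_gap + 1e-12:
            raise InvalidConfigError(
                "left/right leg-crossed means must differ by at most crossed_gap "
                "on every channel"
            )

    @property
    def frames_per_posture(self) -> int:
        return int(round(self.duration_per_posture * self.sampling_rate))

    def mean_matrix(self) -> np.ndarray:
        """Class means as an (8 acquired types, 4 channels) array."""
        return np.array(
            [self.class_means[t.key] for t in ACQUIRED_TYPES], dtype=float
        )

    def to_json(self) -> str:
        d = dict(vars(self))
        d["class_means"] = {k: list(v) for k, v in self.class_means.items()}
        d["other_modes"] = [list(m) for m in self.other_modes]
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "class_means" in d:
            d["class_means"] = {k: tuple(v) for k, v in d["class_means"].items()}
        if "other_modes" in d:
            d["other_modes"] = tuple(tuple(m) for m in d["other_modes"])
        return cls(**d)


def generate_participant_session(
    config: SimConfig, participant: str, seed: int
) -> pd.DataFrame:
    """Simulate one participant's acquisition session.

    Returns a frame table (columns ``t, participant, posture_code,
    sub_variant, c1..c4``) holding ``frames_per_posture`` rows for each of
    the eight acquired posture types, in protocol order, with ``t`` in
    seconds from session start. Deterministic for a fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    scale = (
        rng.normal(1.0, config.participant_scale_sd, size=4)
        if config.participant_scale_sd
        else np.ones(4)
    )
    n = config.frames_per_posture

    blocks = []
    for j, acq in enumerate(ACQUIRED_TYPES):
        if acq.label is Posture.OTHER:
            modes = np.asarray(config.other_modes, dtype=float)
            mu = modes[rng.integers(0, len(modes), size=n)]
        else:
            mu = np.tile(np.asarray(config.class_means[acq.key], dtype=float), (n, 1))
        sd = config.noise_sd * config.noise_scale[acq.key]
        noise = rng.normal(0.0, sd, size=(n, 4)) if sd else 0.0
        values = scale * mu + noise
        t = (np.arange(j * n, (j + 1) * n)) / config.sampling_rate
        block = pd.DataFrame(values, columns=list(CHANNELS))
        block.insert(0, "t", t)
        block.insert(1, "participant", participant)
        block.insert(2, "posture_code", int(acq.label))
        block.insert(3, "sub_variant", acq.sub_variant)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def generate_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate the full cohort: one session per participant.

    Participant ``i`` (1-based) gets id ``P<i>`` and sub-seed
    ``config.seed + i`` so sessions are independent but reproducible.
    """
    config.validate()
    sessions = [
        generate_participant_session(config, f"P{i:02d}", config.seed + i)
        for i in range(1, config.n_participants + 1)
    ]
    return pd.concat(sessions, ignore_index=True)


@dataclass
class ClassificationStream:
    """A per-second stream of posture classifications.

    ``ticks`` is an ordered list of ``(t, posture)`` with integer timestamps
    spaced exactly one second apart — the recognition layer records the
    current posture category once per second.
    """

    ticks: list[tuple[int, Posture]]

    def __post_init__(self) -> None:
        for (t0, _), (t1, _) in zip(self.ticks, self.ticks[1:]):
            if t1 != t0 + 1:
                raise ValueError(f"ticks must be 1 s apart, got {t0} -> {t1}")

    def __len__(self) -> int:
        return len(self.ticks)

    def labels(self) -> list[Posture]:
        return [p for _, p in self.ticks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": [t for t, _ in self.ticks], "posture": [int(p) for _, p in self.ticks]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClassificationStream":
        return cls(
            [(int(t), Posture(int(p))) for t, p in zip(df["t"], df["posture"])]
        )


def generate_stream(
    schedule: Sequence[tuple[Posture | int, int]],
    misclassification_rate: float = 0.0,
    seed: int = 0,
) -> ClassificationStream:
    """Synthesize a recognition-layer output stream from a posture schedule.

    ``schedule`` is a list of ``(posture, duration_seconds)`` segments; the
    stream emits one tick per second (t = 1, 2, ...). Each tick carries the
    scheduled label, replaced with a uniformly random *other* label with
    probability ``misclassification_rate`` — a stand-in for classifier error.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    if not 0 <= misclassification_rate < 1:
        raise ValueError("misclassification_rate must be in [0, 1)")
    labels: list[Posture] = []
    for posture, duration in schedule:
        duration = int(duration)
        if duration <= 0:
            raise ValueError("segment durations must be positive integers")
        labels.extend([Posture(posture)] * duration)

    if misclassification_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(labels)) < misclassification_rate
        offsets = rng.integers(1, len(Posture), size=len(labels))
        labels = [
            Posture((int(p) + int(o)) % len(Posture)) if f else p
            for p, f, o in zip(labels, flip, offsets)
        ]
    return ClassificationStream([(t + 1, p) for t, p in enumerate(labels)])
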