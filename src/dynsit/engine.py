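"""The "Dynamic Sitting" reminder engine.

A state machine consuming one posture classification per second and emitting
haptic-feedback events. Sitting postures are graded into three hazard tiers,
each with its own reminder interval: leg crossed is the most harmful
(serious, 5 min); back bent, forward, backward and other postures are medium
(10 min); upright sitting is the least harmful but still warrants change
(low, 15 min). Over each tier's trailing window the engine counts how often
each posture in the tier was recorded; if any single posture accounts for
strictly more than 70% of the window — a threshold buffering classifier
noise and small in-seat movements — the engine concludes the posture was
maintained and fires a posture-change vibration (800 Hz, 3 s), then clears
that tier's record so reminders do not re-fire every second. Independently,
45 minutes of uninterrupted sitting (any non-stance label; one standing tick
resets the run) fires a sedentary reminder with a longer 7 s vibration.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable

from .postures import SITTING_POSTURES, Posture
from .simulate import ClassificationStream

POSTURE_CHANGE = "posture_change"
SEDENTARY = "sedentary"


@dataclass(frozen=True)
class HazardTier:
    """One hazard level: the postures it covers and its reminder window (s)."""

    name: str
    postures: frozenset[Posture]
    window: int

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("tier window must be positive")
        if Posture.STANCE in self.postures:
            raise ValueError("stance belongs to no hazard tier")


def default_tiers() -> tuple[HazardTier, ...]:
    """Serious 5 min / medium 10 min / low 15 min hazard grading."""
    return (
        HazardTier("serious", frozenset({Posture.LEG_CROSSED}), 300),
        HazardTier(
            "medium",
            frozenset(
                {Posture.BACK_BENT, Posture.FORWARD, Posture.BACKWARD, Posture.OTHER}
            ),
            600,
        ),
        HazardTier("low", frozenset({Posture.UPRIGHT}), 900),
    )


@dataclass(frozen=True)
class EngineConfig:
    """Reminder-engine parameters.

    ``trigger_fraction`` is the share of a tier window a single posture must
    strictly exceed to count as maintained (default 0.70);
    ``sedentary_window`` is the uninterrupted-sitting duration before a
    stand-up reminder (default 2700 s = 45 min). Vibrations are (Hz, s).
    """

    tiers: tuple[HazardTier, ...] = field(default_factory=default_tiers)
    trigger_fraction: float = 0.70
    sedentary_window: int = 2700
    posture_vibration: tuple[float, float] = (800.0, 3.0)
    sedentary_vibration: tuple[float, float] = (800.0, 7.0)

    def __post_init__(self) -> None:
        if not 0 < self.trigger_fraction < 1:
            raise ValueError("trigger_fraction must lie strictly between 0 and 1")
        if self.sedentary_window <= 0:
            raise ValueError("sedentary_window must be positive")
        if any(self.sedentary_window <= t.window for t in self.tiers):
            raise ValueError("sedentary_window must exceed every tier window")
        covered: Counter = Counter()
        for tier in self.tiers:
            covered.update(tier.postures)
        if set(covered) != set(SITTING_POSTURES) or any(v > 1 for v in covered.values()):
            raise ValueError("tiers must partition the six sitting postures")


@dataclass(frozen=True)
class ReminderEvent:
    """A haptic feedback emission."""

    kind: str
    t: int
    posture: Posture | None
    vibration: tuple[float, float]

    def __post_init__(self) -> None:
        if (self.kind == POSTURE_CHANGE) != (self.posture is not None):
            raise ValueError("posture is set iff kind is posture_change")

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "kind": self.kind,
            "posture": None if self.posture is None else int(self.posture),
            "freq_hz": self.vibration[0],
            "dur_s": self.vibration[1],
        }


def vibration_for(kind: str, config: EngineConfig = EngineConfig()) -> tuple[float, float]:
    """Vibration mode (frequency Hz, duration s) for an event kind."""
    if kind == POSTURE_CHANGE:
        return config.posture_vibration
    if kind == SEDENTARY:
        return config.sedentary_vibration
    raise ValueError(f"unknown reminder kind: {kind!r}")


def _trigger_count(trigger_fraction: float, window: int) -> int:
    # strict "more than fraction": fire when count > fraction*window, using an
    # integer threshold robust to float representation of the product
    return int(math.floor(trigger_fraction * window + 1e-9))


class EngineState:
    """Mutable per-session engine state.

    Each tier keeps its own trailing buffer of at most ``window`` recorded
    seconds plus an incremental posture counter, both cleared when the tier
    fires; the sedentary run counts consecutive non-stance ticks.
    """

    def __init__(self, config: EngineConfig):
        self.config = config
        self.buffers: list[deque[Posture]] = [deque() for _ in config.tiers]
        self.counts: list[Counter] = [Counter() for _ in config.tiers]
        self.sitting_run: int = 0
        self.last_t: int | None = None

    def step(self, tick: tuple[int, Posture | int]) -> list[ReminderEvent]:
        """Consume one per-second tick; return events emitted at that tick."""
        t, label = int(tick[0]), Posture(int(tick[1]))
        if self.last_t is not None and t != self.last_t + 1:
            raise ValueError(
                f"ticks must arrive in strict 1 s increments ({self.last_t} -> {t})"
            )
        self.last_t = t
        cfg = self.config
        events: list[ReminderEvent] = []

        fired = False  # at most one posture_change per tick; serious tier first
        for tier, buf, cnt in zip(cfg.tiers, self.buffers, self.counts):
            buf.append(label)
            cnt[label] += 1
            if len(buf) > tier.window:
                old = buf.popleft()
                cnt[old] -= 1
            if fired or len(buf) < tier.window:
                continue
            threshold = _trigger_count(cfg.trigger_fraction, tier.window)
            held = [p for p in sorted(tier.postures) if cnt[p] > threshold]
            if held:
                # highest count wins; ties broken by lowest label code
                best = max(held, key=lambda p: (cnt[p], -int(p)))
                events.append(
                    ReminderEvent(POSTURE_CHANGE, t, best, cfg.posture_vibration)
                )
                buf.clear()
                cnt.clear()
                fired = True

        if label is Posture.STANCE:
            self.sitting_run = 0
        else:
            self.sitting_run += 1
            if self.sitting_run >= cfg.sedentary_window:
                events.append(ReminderEvent(SEDENTARY, t, None, cfg.sedentary_vibration))
                self.sitting_run = 0
        return events


def step(
    state: EngineState, tick: tuple[int, Posture | int], config: EngineConfig | None = None
) -> tuple[EngineState, list[ReminderEvent]]:
    """Functional wrapper over :meth:`EngineState.step`."""
    if config is not None and config is not state.config:
        raise ValueError("config must match the state's config")
    return state, state.step(tick)


def run_session(
    stream: ClassificationStream | Iterable[tuple[int, Posture | int]],
    config: EngineConfig = EngineConfig(),
) -> tuple[list[ReminderEvent], EngineState]:
    """Fold the engine over a whole session; events come out in time order."""
    ticks = stream.ticks if isinstance(stream, ClassificationStream) else stream
    state = EngineState(config)
    events: list[ReminderEvent] = []
    for tick in ticks:
        events.extend(state.step(tick))
    return events, state


def run_session_bruteforce(
    stream: ClassificationStream | Iterable[tuple[int, Posture | int]],
    config: EngineConfig = EngineConfig(),
) -> list[ReminderEvent]:
    """Reference engine that re-scans full per-tier records at every tick.

    Same semantics as :func:`run_session`, implemented with none of the
    incremental bookkeeping — an oracle for equivalence testing.
    """
    import numpy as np

    ticks = list(stream.ticks if isinstance(stream, ClassificationStream) else stream)
    times = [int(t) for t, _ in ticks]
    labels = np.array([int(p) for _, p in ticks], dtype=np.int64)
    for t0, t1 in zip(times, times[1:]):
        if t1 != t0 + 1:
            raise ValueError("gapped timestamps")

    reset_at = [0 for _ in config.tiers]  # index of first record since reset
    sitting_run = 0
    events: list[ReminderEvent] = []
    for i, (t, _) in enumerate(ticks):
        label = Posture(int(labels[i]))
        fired = False
        for j, tier in enumerate(config.tiers):
            n_records = i + 1 - reset_at[j]
            if fired or n_records < tier.window:
                continue
            window = labels[i + 1 - tier.window : i + 1]
            counts = np.bincount(window, minlength=len(Posture))
            threshold = _trigger_count(config.trigger_fraction, tier.window)
            held = [p for p in sorted(tier.postures) if counts[p] > threshold]
            if held:
                best = max(held, key=lambda p: (counts[p], -int(p)))
                events.append(
                    ReminderEvent(POSTURE_CHANGE, t, best, config.posture_vibration)
                )
                reset_at[j] = i + 1
                fired = True
        if label is Posture.STANCE:
            sitting_run = 0
        else:
            sitting_run += 1
            if sitting_run >= config.sedentary_window:
                events.append(ReminderEvent(SEDENTARY, t, None, config.sedentary_vibration))
                sitting_run = 0
    return events


def recover_trigger_threshold(
    config: EngineConfig = EngineConfig(),
    tier: HazardTier | str = "serious",
) -> float:
    """Locate the firing threshold empirically by bisection.

    Constructs synthetic windows of the tier's length containing ``k`` ticks
    of a tier posture, the remainder cycled over all sitting postures outside
    the tier, and bisects ``k`` on the fire/no-fire boundary. Returns the
    largest non-firing fraction — the configured trigger threshold, recovered
    from behaviour alone.
    """
    if isinstance(tier, str):
        matches = [t for t in config.tiers if t.name == tier]
        if not matches:
            raise ValueError(f"no tier named {tier!r}")
        tier = matches[0]
    target = min(tier.postures)
    fillers = sorted(SITTING_POSTURES - tier.postures)

    def fires(k: int) -> bool:
        n_fill = tier.window - k
        labels = [fillers[i % len(fillers)] for i in range(n_fill)] + [target] * k
        ticks = [(i + 1, p) for i, p in enumerate(labels)]
        events, _ = run_session(ticks, config)
        return any(
            e.kind == POSTURE_CHANGE and e.posture in tier.postures for e in events
        )

    lo, hi = 0, tier.window  # lo never fires; hi always does
    if not fires(hi):
        raise RuntimeError("engine did not fire on a pure-posture window")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return lo / tier.window
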