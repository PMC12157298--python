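import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynsit import (
    EngineConfig,
    EngineState,
    HazardTier,
    Posture,
    ReminderEvent,
    generate_stream,
    recover_trigger_threshold,
    run_session,
    run_session_bruteforce,
    vibration_for,
)
from dynsit.engine import POSTURE_CHANGE, SEDENTARY

SITTING = [p for p in Posture if p is not Posture.STANCE]


def constant(posture, seconds):
    return generate_stream([(posture, seconds)], 0.0)


class TestFirstFireTimes:
    @pytest.mark.parametrize(
        "posture,expected_t",
        [
            (Posture.LEG_CROSSED, 300),  # serious tier: 5 min
            (Posture.BACK_BENT, 600),  # medium tier: 10 min
            (Posture.FORWARD, 600),
            (Posture.BACKWARD, 600),
            (Posture.OTHER, 600),
            (Posture.UPRIGHT, 900),  # low tier: 15 min
        ],
    )
    def test_constant_stream_first_posture_reminder(self, posture, expected_t):
        events, _ = run_session(constant(posture, expected_t + 200))
        posture_events = [e for e in events if e.kind == POSTURE_CHANGE]
        assert posture_events[0].t == expected_t
        assert posture_events[0].posture is posture

    def test_constant_stance_never_fires(self):
        events, _ = run_session(constant(Posture.STANCE, 3000))
        assert events == []

    def test_alternating_postures_never_trigger(self):
        """Two postures at 50% each stay below the 70% trigger fraction."""
        ticks = [(t + 1, SITTING[t % 2]) for t in range(2000)]
        events, _ = run_session(ticks)
        assert [e for e in events if e.kind == POSTURE_CHANGE] == []

    def test_sedentary_fires_at_45_minutes(self):
        schedule = [(p, 450) for p in SITTING]  # 2700 s, no standing
        events, _ = run_session(generate_stream(schedule, 0.0))
        sedentary = [e for e in events if e.kind == SEDENTARY]
        assert sedentary[0].t == 2700

    def test_reset_after_fire_gives_periodic_reminders(self):
        events, _ = run_session(constant(Posture.UPRIGHT, 2700))
        assert [(e.t, e.kind) for e in events] == [
            (900, POSTURE_CHANGE),
            (1800, POSTURE_CHANGE),
            (2700, POSTURE_CHANGE),
            (2700, SEDENTARY),
        ]

    def test_single_medium_fire_at_600(self):
        events, _ = run_session(constant(Posture.BACK_BENT, 600))
        assert [(e.t, e.kind) for e in events] == [(600, POSTURE_CHANGE)]

    def test_stance_interruption_resets_sedentary_timer(self):
        # one standing tick every 2699 s: sitting runs never reach 2700
        segments = []
        for _ in range(4):
            segments += [(Posture.UPRIGHT, 2699), (Posture.STANCE, 1)]
        events, _ = run_session(generate_stream(segments, 0.0))
        assert [e for e in events if e.kind == SEDENTARY] == []


class TestTriggerSemantics:
    def test_exactly_70_percent_does_not_fire(self):
        """The threshold is strict: 210/300 leg-crossed ticks stay silent."""
        fill = [Posture.UPRIGHT, Posture.BACK_BENT, Posture.FORWARD]
        labels = [fill[i % 3] for i in range(90)] + [Posture.LEG_CROSSED] * 210
        events, _ = run_session([(i + 1, p) for i, p in enumerate(labels)])
        assert [e for e in events if e.posture is Posture.LEG_CROSSED] == []

    def test_just_above_70_percent_fires(self):
        fill = [Posture.UPRIGHT, Posture.BACK_BENT, Posture.FORWARD]
        labels = [fill[i % 3] for i in range(89)] + [Posture.LEG_CROSSED] * 211
        events, _ = run_session([(i + 1, p) for i, p in enumerate(labels)])
        assert any(e.posture is Posture.LEG_CROSSED for e in events)

    def test_full_window_fires_69_percent_does_not(self):
        pure, _ = run_session(constant(Posture.LEG_CROSSED, 300))
        assert len(pure) == 1
        labels = [Posture.UPRIGHT] * 93 + [Posture.LEG_CROSSED] * 207  # 69%
        partial, _ = run_session([(i + 1, p) for i, p in enumerate(labels)])
        assert partial == []

    def test_recovered_threshold_is_70_percent(self):
        assert recover_trigger_threshold(EngineConfig(), "serious") == pytest.approx(0.70)

    @pytest.mark.parametrize("fraction", [0.5, 0.9])
    def test_recovered_threshold_tracks_config(self, fraction):
        cfg = EngineConfig(trigger_fraction=fraction)
        assert recover_trigger_threshold(cfg, "serious") == pytest.approx(fraction)

    def test_recovery_works_for_all_tiers(self):
        cfg = EngineConfig()
        for tier in cfg.tiers:
            assert recover_trigger_threshold(cfg, tier.name) == pytest.approx(0.70)

    def test_raising_trigger_fraction_never_adds_events(self):
        stream = generate_stream(
            [(Posture.LEG_CROSSED, 1200), (Posture.UPRIGHT, 1200)], 0.15, seed=3
        )
        lo, _ = run_session(stream, EngineConfig(trigger_fraction=0.6))
        hi, _ = run_session(stream, EngineConfig(trigger_fraction=0.8))
        n_lo = sum(1 for e in lo if e.kind == POSTURE_CHANGE)
        n_hi = sum(1 for e in hi if e.kind == POSTURE_CHANGE)
        assert n_hi <= n_lo


class TestVibration:
    def test_posture_change_mode(self):
        assert vibration_for(POSTURE_CHANGE) == (800.0, 3.0)

    def test_sedentary_mode_longer(self):
        freq, dur = vibration_for(SEDENTARY)
        assert (freq, dur) == (800.0, 7.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            vibration_for("buzz")

    def test_events_carry_their_kind_vibration(self):
        events, _ = run_session(constant(Posture.UPRIGHT, 2700))
        for e in events:
            assert e.vibration == vibration_for(e.kind)


class TestStateInvariants:
    def test_gapped_timestamps_rejected(self):
        state = EngineState(EngineConfig())
        state.step((1, Posture.UPRIGHT))
        with pytest.raises(ValueError):
            state.step((3, Posture.UPRIGHT))

    def test_no_event_before_window_elapsed(self):
        events, _ = run_session(constant(Posture.LEG_CROSSED, 299))
        assert events == []

    def test_at_most_one_posture_event_per_tick_serious_first(self):
        # leg-crossed saturates both its own and (as history) other buffers;
        # build a stream where serious and low tiers would both be eligible
        labels = [Posture.UPRIGHT] * 899 + [Posture.LEG_CROSSED] * 300
        labels += [Posture.UPRIGHT] * 1
        events, _ = run_session([(i + 1, p) for i, p in enumerate(labels)])
        by_tick = {}
        for e in events:
            if e.kind == POSTURE_CHANGE:
                by_tick.setdefault(e.t, []).append(e)
        assert all(len(v) == 1 for v in by_tick.values())

    def test_event_rate_bound(self):
        """At most one posture reminder per tier window per reset cycle."""
        events, _ = run_session(constant(Posture.LEG_CROSSED, 3000))
        serious = [e.t for e in events if e.posture is Posture.LEG_CROSSED]
        assert serious == [300 * k for k in range(1, 11)]

    def test_tiers_must_partition_sitting_postures(self):
        bad = (
            HazardTier("serious", frozenset({Posture.LEG_CROSSED}), 300),
            HazardTier("low", frozenset({Posture.UPRIGHT}), 900),
        )
        with pytest.raises(ValueError):
            EngineConfig(tiers=bad)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_incremental_matches_bruteforce_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        schedule = []
        remaining = 7200  # 2 h
        while remaining > 0:
            d = int(rng.integers(1, 400))
            d = min(d, remaining)
            schedule.append((Posture(int(rng.integers(0, 7))), d))
            remaining -= d
        stream = generate_stream(schedule, 0.1, seed=seed)
        incremental, _ = run_session(stream)
        assert incremental == run_session_bruteforce(stream)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 6), st.integers(1, 500)), min_size=1, max_size=12))
    def test_equivalence_on_arbitrary_short_schedules(self, raw):
        cfg = EngineConfig(
            tiers=(
                HazardTier("serious", frozenset({Posture.LEG_CROSSED}), 30),
                HazardTier(
                    "medium",
                    frozenset({Posture.BACK_BENT, Posture.FORWARD, Posture.BACKWARD,
                               Posture.OTHER}),
                    60,
                ),
                HazardTier("low", frozenset({Posture.UPRIGHT}), 90),
            ),
            sedentary_window=200,
        )
        stream = generate_stream([(Posture(p), d) for p, d in raw], 0.0)
        incremental, _ = run_session(stream, cfg)
        assert incremental == run_session_bruteforce(stream, cfg)
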