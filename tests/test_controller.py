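"""Selection controller rules, attempt timing, and movement planning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthobci.controller import (ControllerConfig, ControllerState, Decision,
                                 movement_command_frames, plan_movement,
                                 run_attempt, update)

T, N, A = "target", "non-target", "artifact"


def _feed(labels_by_event, config=None):
    """Feed (option, label) pairs; return list of decisions."""
    cfg = config or ControllerConfig()
    state = ControllerState(config=cfg)
    decisions = []
    for option, label in labels_by_event:
        state, d = update(state, option, label, cfg)
        decisions.append(d)
    return state, decisions


class TestUpdate:
    def test_consistent_target_fires_on_fifth_valid_epoch(self):
        # Round-robin flashing, option 2 always target, others non-target:
        # the selection must fire exactly when option 2 gets its 5th label.
        events = []
        for _ in range(6):
            for o in range(6):
                events.append((o, T if o == 2 else N))
        _, decisions = _feed(events)
        fired = [i for i, d in enumerate(decisions) if d.kind == "select"]
        # option 2 is the third flash of each round: 5th label at index 4*6+2.
        assert fired and fired[0] == 4 * 6 + 2
        assert decisions[fired[0]].option_id == 2

    def test_all_nontarget_never_selects(self):
        events = [(o % 6, N) for o in range(300)]
        _, decisions = _feed(events)
        assert all(d.kind == "none" for d in decisions)

    def test_forty_percent_target_fraction_insufficient(self):
        # Buffer with 4 targets / 6 non-targets: 40% < 70%.
        events = [(0, N)] * 6 + [(0, T)] * 4
        state, decisions = _feed(events)
        assert all(d.kind == "none" for d in decisions)
        assert state.counts(0) == (4, 6)

    def test_artifacts_only_increment_discard_counter(self):
        events = [(1, A)] * 7 + [(1, T)] * 4
        state, decisions = _feed(events)
        assert state.discarded_artifacts == 7
        assert state.counts(1) == (4, 0)
        assert all(d.kind == "none" for d in decisions)  # min_epochs unmet

    def test_other_option_below_nontarget_threshold_vetoes(self):
        # Option 0 perfect, but option 1 is half target: 50% < 60% veto bar.
        events = [(1, T), (1, N)] + [(0, T)] * 6
        _, decisions = _feed(events)
        assert all(d.kind == "none" for d in decisions)
        # Same stream with option 1 mostly non-target passes.
        events = [(1, N), (1, N), (1, T)] + [(0, T)] * 6
        _, decisions = _feed(events)
        assert any(d.kind == "select" and d.option_id == 0 for d in decisions)

    def test_empty_buffers_cannot_veto(self):
        # Only option 3 has flashed: it may be selected alone.
        _, decisions = _feed([(3, T)] * 5)
        assert decisions[-1].kind == "select"
        assert decisions[-1].option_id == 3

    def test_ring_buffer_keeps_last_window_labels(self):
        cfg = ControllerConfig()
        # 10 non-targets then 7 targets: buffer = last 10 = (7 T, 3 N) = 70%.
        events = [(0, N)] * 10 + [(0, T)] * 7
        state, decisions = _feed(events)
        assert decisions[-1].kind == "select"

    def test_no_selection_before_min_epochs(self):
        for labels in itertools.product([T, N], repeat=4):
            _, decisions = _feed([(0, lab) for lab in labels])
            assert all(d.kind == "none" for d in decisions)

    def test_selection_resets_buffers(self):
        state, decisions = _feed([(2, T)] * 5)
        assert decisions[-1].kind == "select"
        assert all(len(buf) == 0 for buf in state.buffers)

    def test_unknown_option_or_label_rejected(self):
        state = ControllerState()
        with pytest.raises(ValueError, match="option_id"):
            update(state, 6, T)
        with pytest.raises(ValueError, match="label"):
            update(state, 0, "maybe")


def test_default_thresholds_guarantee_unique_selection():
    """Exhaustive check over two options' buffer contents (window 10): the
    70%/60% thresholds never let two options qualify simultaneously."""
    cfg = ControllerConfig()

    def qualifies(own, others):
        n_t, n_nt = own
        total = n_t + n_nt
        if total < cfg.min_epochs or n_t / total < cfg.target_threshold:
            return False
        for m_t, m_nt in others:
            m = m_t + m_nt
            if m > 0 and m_nt / m < cfg.nontarget_threshold:
                return False
        return True

    contents = [(t, n) for t in range(11) for n in range(11 - t)]
    for buf_a in contents:
        for buf_b in contents:
            both = qualifies(buf_a, [buf_b]) and qualifies(buf_b, [buf_a])
            assert not both, (buf_a, buf_b)


def test_config_validation():
    with pytest.raises(ValueError):
        ControllerConfig(min_epochs=11)
    with pytest.raises(ValueError):
        ControllerConfig(target_threshold=0.4)
    with pytest.raises(ValueError, match="thresholds"):
        ControllerConfig(nontarget_threshold=0.5)


class TestRunAttempt:
    def test_engineered_selection_time(self):
        stream = [(0.8 + 0.15 * i, i % 6, T if i % 6 == 4 else N)
                  for i in range(40)]
        # Option 4's 5th label arrives at event index 4*6+4 = 28.
        result = run_attempt(iter(stream))
        assert result.selected == 4
        assert result.selection_time_s == pytest.approx(0.8 + 0.15 * 28)

    def test_empty_stream_times_out(self):
        result = run_attempt(iter([]))
        assert result.timed_out and result.selected is None
        assert result.selection_time_s == 30.0

    def test_random_labels_show_both_outcomes_across_seeds(self):
        outcomes = set()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            stream = [(0.15 * i, int(rng.integers(6)),
                       T if rng.random() < 0.5 else N) for i in range(200)]
            result = run_attempt(iter(stream))
            outcomes.add(result.timed_out)
        assert outcomes == {True, False}

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            run_attempt(iter([(1.0, 0, N), (0.5, 1, N)]))

    @given(st.lists(st.tuples(st.integers(0, 5), st.sampled_from([T, N, A])),
                    max_size=120))
    @settings(max_examples=30, deadline=None)
    def test_replay_determinism(self, events):
        stream = [(0.15 * i, o, lab) for i, (o, lab) in enumerate(events)]
        r1 = run_attempt(iter(stream))
        r2 = run_attempt(iter(stream))
        assert r1 == r2


class TestMovementPlanning:
    def test_single_finger_options(self):
        plan = plan_movement(0)
        assert plan.actuators == ("thumb",)
        assert plan.duration_s == 4.0
        assert plan_movement(3).actuators == ("ring",)

    def test_option_five_moves_all_digits(self):
        assert plan_movement(5).actuators == ("thumb", "index", "middle",
                                              "ring", "little")

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="option"):
            plan_movement(7)

    def test_command_frames_cover_duration_and_actuators(self):
        frames = movement_command_frames(plan_movement(1))
        assert len(frames) == 40  # 4 s at 10 Hz
        peak = max(f["positions"]["index"] for f in frames)
        assert peak == pytest.approx(1.0, abs=0.06)  # triangle apex off-grid
        assert all(f["positions"]["thumb"] == 0.0 for f in frames)
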