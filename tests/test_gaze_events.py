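import numpy as np
import pytest

import infoseek as ik
from infoseek.core_session import Condition, Trial, ValidationError
from infoseek.gaze_events import (GazeState, NOMINAL_CENTERS, detect_licks,
                                  gaze_on_flags, lick_threshold,
                                  select_balanced_controls)
from infoseek.synthetic_data import GazeBehaviorSpec, gen_lick_trace


def _square_wave_trial(on_start=1.0, on_end=2.0, duration=3.0,
                       far_deg=10.0, blink_at=None):
    """Gaze far from the CS except within [on_start, on_end)."""
    n_ms = int(1000 * duration)
    gaze = np.zeros((n_ms, 3))
    gaze[:, 0] = far_deg
    a, b = int(on_start * 1000), int(on_end * 1000)
    gaze[a:b, 0] = 0.0
    if blink_at is not None:
        m = int(blink_at * 1000)
        gaze[m:m + 10, 2] = 1.0
    cond = Condition(task_id="standard_uncertainty", cs_kind="standard",
                     reward_prob=0.5)
    return Trial(condition=cond, duration=duration, t_outcome=duration,
                 spikes=np.array([]), gaze=gaze)


class TestDetectGazeShifts:
    def _events(self, trial):
        state = GazeState(flags=gaze_on_flags(trial, (0.0, 0.0)),
                          center=(0.0, 0.0))
        return ik.detect_gaze_shifts(trial, state)

    def test_square_wave_produces_one_onto_and_one_off(self):
        ev = self._events(_square_wave_trial())
        kinds = {(e.direction, e.time) for e in ev}
        assert ("onto", 0.960) in kinds
        assert ("off", 2.000) in kinds
        assert len(ev) == 2

    def test_gaze_never_on_stimulus_gives_no_events(self):
        tr = _square_wave_trial(on_start=0.0, on_end=0.0)
        assert self._events(tr) == []

    def test_blink_shortly_before_shift_rejects_event(self):
        ev = self._events(_square_wave_trial(blink_at=1.95))
        assert all(e.direction != "off" for e in ev)

    def test_translation_equivariance(self):
        t1 = _square_wave_trial(on_start=1.0, on_end=2.0)
        t2 = _square_wave_trial(on_start=1.2, on_end=2.2)
        e1 = sorted((e.direction, e.time) for e in self._events(t1))
        e2 = sorted((e.direction, e.time) for e in self._events(t2))
        assert [(d, round(t + 0.2, 3)) for d, t in e1] == \
            [(d, round(t, 3)) for d, t in e2]

    def test_small_excursion_rejected(self):
        # stays only 4 deg away: not a genuine shift off the stimulus
        tr = _square_wave_trial(far_deg=4.0)
        assert self._events(tr) == []


class TestSelectBalancedControls:
    def test_all_positive_selects_only_smallest(self):
        assert select_balanced_controls([0.1, 0.3]) == [0]

    def test_alternating_signs_selects_all_in_order(self):
        assert select_balanced_controls([-0.05, 0.1, -0.2, 0.3]) == \
            [0, 1, 2, 3]

    def test_empty_candidates(self):
        assert select_balanced_controls([]) == []

    def test_selection_follows_the_iterative_rule(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            diffs = rng.normal(0, 1, rng.integers(1, 12))
            sel = select_balanced_controls(list(diffs))
            assert sel
            # first pick is the global minimum magnitude
            assert abs(diffs[sel[0]]) == pytest.approx(np.min(np.abs(diffs)))
            # each later pick opposes the running mean of prior selections
            for k in range(1, len(sel)):
                mean = np.mean([diffs[i] for i in sel[:k]])
                if mean != 0:
                    assert diffs[sel[k]] * mean < 0


class TestMatchControls:
    def test_matching_balances_distances(self, modulated_session):
        events = ik.detect_and_match_shifts(modulated_session)
        assert len(events) > 100
        diffs = np.concatenate([e.control_diffs for e in events])
        assert abs(diffs.mean()) < 0.05
        assert all(len(e.controls) >= 1 for e in events)

    def test_controls_share_condition_and_time(self, modulated_session):
        s = modulated_session
        events = ik.detect_and_match_shifts(s)
        ev = events[0]
        cond = s.trials[ev.trial_index].condition
        for j, t in ev.controls:
            assert s.trials[j].condition == cond
            assert t == ev.time
            assert j != ev.trial_index


class TestCalibration:
    def test_samples_at_nominal_center_recovered(self, std_session):
        c = ik.calibrate_gaze_window(std_session, "center")
        assert abs(c[0]) <= 0.25 and abs(c[1]) <= 0.25

    def test_known_offset_recovered(self, plain_gaze):
        spec = ik.uncertainty_neuron_spec()
        s = ik.gen_uncertainty_session(spec, plain_gaze, 10, seed=51)
        for tr in s.trials:
            tr.gaze[:, 0] += 1.0
        c = ik.calibrate_gaze_window(s, "center")
        assert c[0] == pytest.approx(1.0, abs=0.3)

    def test_no_nearby_samples_falls_back_with_warning(self):
        tr = _square_wave_trial(on_start=0.0, on_end=0.0, far_deg=20.0)
        s = ik.NeuronSession(neuron_id="n", area="ACC", animal_id="a",
                             trials=[tr])
        with pytest.warns(UserWarning, match="nominal"):
            c = ik.calibrate_gaze_window(s, "center")
        assert c == NOMINAL_CENTERS["center"]


class TestGazeStateActivityCompare:
    def test_gain_modulated_neuron_on_exceeds_off_when_uncertain(
            self, modulated_session):
        s = modulated_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        res = ik.gaze_state_activity_compare(s, act)
        s.sign_S = None
        assert res is not None
        unc_diff = np.mean([on - off for c, (on, off) in res.items()
                            if c.uncertain])
        assert unc_diff > 0

    def test_unmodulated_neuron_difference_near_zero(self, std_session):
        s = std_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        res = ik.gaze_state_activity_compare(s, act)
        s.sign_S = None
        diffs = [on - off for on, off in res.values()]
        assert abs(np.mean(diffs)) < 0.25

    def test_constant_gaze_excludes_neuron(self, std_session):
        s = std_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        # force every trial's gaze far away: no ms has both states
        far = {"center": (50.0, 50.0)}
        assert ik.gaze_state_activity_compare(s, act, centers=far) is None
        s.sign_S = None


class TestShiftAlignedActivity:
    def test_null_generator_window_means_near_zero(self, std_session):
        s = std_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        events = ik.detect_and_match_shifts(s)
        res = ik.shift_aligned_activity(events, s, act)
        s.sign_S = None
        assert res is not None
        for cell in res.values():
            for v in cell["windows"].values():
                assert abs(v) < 0.5  # self-subtraction null, ~40 events/cell

    def test_gain_ramp_neuron_pre_window_pattern(self, modulated_session):
        s = modulated_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        events = ik.detect_and_match_shifts(s)
        res = ik.shift_aligned_activity(events, s, act)
        s.sign_S = None
        pre = (-0.4, -0.1)
        assert res[("onto", "uncertain")]["windows"][pre] > 0
        assert res[("off", "uncertain")]["windows"][pre] < 0
        # modulation is gain-like: certain conditions move less
        assert res[("onto", "uncertain")]["windows"][pre] > \
            res[("onto", "certain-no-reward")]["windows"][pre]

    def test_on_off_difference_grows_across_windows(self, plain_gaze):
        # generator whose modulation builds up through and after the shift
        spec = ik.uncertainty_neuron_spec(w_gain=1.0, mu=-0.1, sigma=0.2)
        s = ik.gen_uncertainty_session(spec, plain_gaze, 30, seed=106)
        s.sign_S = 1
        act = ik.normalize_activity(s)
        events = ik.detect_and_match_shifts(s)
        res = ik.shift_aligned_activity(events, s, act)
        s.sign_S = None
        diffs = [res[("onto", "uncertain")]["windows"][w]
                 - res[("off", "uncertain")]["windows"][w]
                 for w in [(-0.4, -0.1), (-0.1, 0.1), (0.1, 0.4)]]
        assert diffs[0] < diffs[1] < diffs[2]

    def test_pre_windows_exclude_post_shift_samples(self):
        from infoseek.gaze_events import _aligned_trace
        traces = np.arange(3000.0)[None, :]
        seg = _aligned_trace(traces, 0, 1.0, 0.4, 0.4)
        times = np.arange(-400, 400)
        pre = seg[times < -100]
        assert pre.max() < 1000 - 100  # all samples from before the shift


class TestDetectLicks:
    def test_noise_only_flags_below_ten_percent(self):
        base = [gen_lick_trace(3.0, [], noise_sd=1.0, seed=i)
                for i in range(12)]
        thr = lick_threshold(base)
        frac = np.mean([detect_licks(t, threshold=thr).mean()
                        for t in base])
        assert frac < 0.10

    def test_burst_detected_within_filter_delay(self):
        base = [gen_lick_trace(3.0, [], noise_sd=1.0, seed=100 + i)
                for i in range(10)]
        tr = gen_lick_trace(3.0, [(1.0, 1.5)], noise_sd=1.0, seed=5)
        flags = detect_licks(tr, baseline_traces=base)
        on = np.flatnonzero(flags)
        assert on.size > 0
        assert on.min() / 1000.0 >= 0.95 and on.max() / 1000.0 <= 1.65
        assert flags[1100:1400].any()

    def test_all_zero_signal_flags_nothing(self):
        base = [gen_lick_trace(3.0, [], noise_sd=1.0, seed=i)
                for i in range(5)]
        thr = lick_threshold(base)
        assert not detect_licks(np.zeros(3000), threshold=thr).any()

    def test_missing_trace_errors(self):
        with pytest.raises(ValidationError):
            detect_licks(None)


class TestBehavioralIndexes:
    def test_extreme_info_gaze_gives_maximal_cue_index(self, plain_gaze):
        spec = ik.info_neuron_spec(hypothesis=0)
        s = ik.gen_info_session(spec, plain_gaze, 6, seed=61)
        for tr in s.trials:
            c = tr.condition
            on = c.cs_kind == "info" and c.uncertain
            tr.gaze[:, 0] = 0.0 if on else 10.0
            tr.gaze[:, 2] = 0.0
        idx = ik.behavioral_anticipation_indexes(s, n_perms=120, seed=0)
        assert idx.cue_index == pytest.approx(0.5)

    def test_condition_independent_gaze_near_zero(self, plain_gaze):
        spec = ik.info_neuron_spec(hypothesis=0)
        s = ik.gen_info_session(spec, plain_gaze, 25, seed=62)
        idx = ik.behavioral_anticipation_indexes(s, n_perms=200, seed=0)
        assert abs(idx.cue_index) < 0.2
        assert idx.p_cue > 0.01

    def test_uncertainty_attracted_gaze_positive_indexes(self, attracted_gaze):
        spec = ik.info_neuron_spec(hypothesis=0)
        s = ik.gen_info_session(spec, attracted_gaze, 100, seed=63)
        idx = ik.behavioral_anticipation_indexes(s, n_perms=1000, seed=0)
        assert idx.cue_index > 0 and idx.p_cue < 0.001
        assert idx.outcome_index > 0 and idx.p_outcome < 0.05


class TestGazeProbabilityTimecourse:
    def test_all_on_gaze_gives_probability_one(self, plain_gaze):
        spec = ik.info_neuron_spec(hypothesis=0)
        s = ik.gen_info_session(spec, plain_gaze, 3, seed=64)
        for tr in s.trials:
            tr.gaze[:, :2] = 0.0
            tr.gaze[:, 2] = 0.0
        res = ik.gaze_probability_timecourse([s])
        for mean, _ in res.values():
            assert np.all(mean == 1.0)

    def test_markov_occupancy_matches_analytic(self, plain_gaze):
        spec = ik.info_neuron_spec(hypothesis=0)
        sessions = [ik.gen_info_session(spec, plain_gaze, 10, seed=70 + i)
                    for i in range(12)]
        res = ik.gaze_probability_timecourse(sessions)
        p_on = 0.002 / (0.002 + 0.0015)  # stationary occupancy
        grand = []
        for mean, _ in res.values():
            grand.append(mean.mean())
        se = np.std(grand, ddof=1) / np.sqrt(len(grand))
        assert abs(np.mean(grand) - p_on) < max(3 * se, 0.05)
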