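import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import infoseek as ik
from infoseek.core_session import AnalysisWindow, ValidationError
from infoseek.signal_analysis import (_causal_boxcar, _mwu_columns,
                                      rank_sum_p, window_rates)
from infoseek.synthetic_data import (GazeBehaviorSpec, NeuronSpec,
                                     PROFILE_BIN_S, STANDARD_T_OUTCOME,
                                     uncertainty_conditions)

from conftest import roc_brute_force


# ---------------------------------------------------------------------------
# ROC area
# ---------------------------------------------------------------------------

class TestRocArea:
    def test_identical_samples_give_half(self):
        assert ik.roc_area([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_worked_example_with_ties(self):
        # brute force over all 9 pairs: 8 wins + 1 tie -> 8.5/9
        assert ik.roc_area([1, 2, 3], [0, 0, 1]) == pytest.approx(8.5 / 9)

    def test_complete_separation(self):
        assert ik.roc_area([0, 1], [5, 6]) == 0.0
        assert ik.roc_area([5, 6], [0, 1]) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=5)
        assert ik.roc_area(x, y) == pytest.approx(1.0 - ik.roc_area(y, x))

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            ik.roc_area([], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=8),
           st.lists(st.integers(0, 4), min_size=1, max_size=8))
    def test_matches_exhaustive_pair_counting(self, x, y):
        assert ik.roc_area(x, y) == pytest.approx(roc_brute_force(x, y))


def test_mwu_columns_agree_with_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(9, 20))
    y = rng.normal(0.5, 1.0, size=(7, 20))
    x[:, 5] = 1.0  # tied column
    y[:, 5] = 1.0
    auc, p = _mwu_columns(x, y)
    for j in [0, 5, 13]:
        assert auc[j] == pytest.approx(ik.roc_area(x[:, j], y[:, j]))
        assert p[j] == pytest.approx(rank_sum_p(x[:, j], y[:, j]), abs=1e-9)


# ---------------------------------------------------------------------------
# Normalized uncertainty signal algebra
# ---------------------------------------------------------------------------

class TestNormalizedUncertaintySignal:
    def test_direct_substitution(self):
        assert ik.normalized_uncertainty_signal(0.8, -1) == pytest.approx(0.2)

    def test_half_is_fixed_point(self):
        for s in (-1, 1):
            assert ik.normalized_uncertainty_signal(0.5, s) == 0.5

    def test_involution_under_negative_sign(self):
        rng = np.random.default_rng(1)
        for u in rng.random(50):
            twice = ik.normalized_uncertainty_signal(
                ik.normalized_uncertainty_signal(u, -1), -1)
            assert twice == pytest.approx(u)


# ---------------------------------------------------------------------------
# Exponential smoothing
# ---------------------------------------------------------------------------

class TestSmoothExponential:
    def test_empty_train_gives_zero_rate(self):
        assert np.all(ik.smooth_exponential(np.array([]), 500) == 0)

    def test_impulse_response_is_causal_with_30ms_decay(self):
        r = ik.smooth_exponential(np.array([0.2]), 1000)
        assert np.all(r[:200] == 0)
        peak = r[200]
        assert peak > 0
        # decay by 1/e after one time constant (30 ms)
        assert r[230] == pytest.approx(peak / np.e, rel=0.05)

    def test_unbiased_for_constant_rate(self):
        rng = np.random.default_rng(2)
        means = []
        for _ in range(100):
            spikes = np.sort(rng.uniform(0, 1.0, rng.poisson(20)))
            means.append(ik.smooth_exponential(spikes, 1000)[300:].mean())
        se = np.std(means, ddof=1) / 10
        assert abs(np.mean(means) - 20.0) < 3 * se + 0.2


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalizeActivity:
    def test_constant_neuron_raises_zero_sd(self):
        conds = uncertainty_conditions()
        n_bins = int(round(2.7 / PROFILE_BIN_S))
        spec = NeuronSpec({c: np.zeros(n_bins) for c in conds})
        s = ik.gen_uncertainty_session(spec, GazeBehaviorSpec(), 3, seed=0)
        s.sign_S = 1
        with pytest.raises(ValidationError, match="SD"):
            ik.normalize_activity(s)

    def test_sign_flip_negates(self, std_session):
        s = std_session
        s.sign_S = 1
        a_pos = ik.normalize_activity(s)
        s.sign_S = -1
        a_neg = ik.normalize_activity(s)
        s.sign_S = None
        assert np.allclose(a_pos.traces, -a_neg.traces)

    def test_condition_average_vector_is_standardized(self, std_session):
        s = std_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        cond_of = [t.condition for t in s.trials]
        means = []
        for c in s.conditions():
            idx = [i for i, cc in enumerate(cond_of) if cc == c]
            means.append(act.traces[idx].mean(axis=0))
        concat = np.concatenate(means)
        s.sign_S = None
        assert concat.mean() == pytest.approx(0.0, abs=1e-9)
        assert concat.std() == pytest.approx(1.0, abs=1e-9)

    def test_renormalize_reproduces_exactly(self, std_session):
        s = std_session
        s.sign_S = 1
        act = ik.normalize_activity(s)
        raw = act.traces * act.sd * act.sign_S + act.mean
        assert np.allclose(act.renormalize(raw), act.traces)
        s.sign_S = None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassifyUncertaintyNeuron:
    def test_excited_neuron_included_positive(self, std_session):
        included, sign = ik.classify_uncertainty_neuron(std_session)
        assert included and sign == 1

    def test_inhibited_neuron_included_negative(self, plain_gaze):
        peaks = {0.0: 20.0, 0.25: 12.0, 0.5: 6.0, 0.75: 12.0, 1.0: 20.0}
        spec = ik.uncertainty_neuron_spec(peak_rates=peaks, base_rate=20.0,
                                          sign_S=-1)
        s = ik.gen_uncertainty_session(spec, plain_gaze, 20, seed=104)
        included, sign = ik.classify_uncertainty_neuron(s)
        assert included and sign == -1

    def test_flat_neuron_usually_excluded(self, plain_gaze):
        hits = 0
        for seed in range(8):
            spec = ik.uncertainty_neuron_spec(
                peak_rates={p: 8.0 for p in (0.0, 0.25, 0.5, 0.75, 1.0)},
                base_rate=8.0)
            s = ik.gen_uncertainty_session(spec, plain_gaze, 15, seed=200 + seed)
            included, _ = ik.classify_uncertainty_neuron(s)
            hits += included
        assert hits <= 2  # ~5% false-positive rate per test

    def test_info_task_classification(self, info_session_h1):
        included, sign = ik.classify_uncertainty_neuron(info_session_h1)
        assert included and sign == 1


# ---------------------------------------------------------------------------
# Anticipation indexes
# ---------------------------------------------------------------------------

class TestAnticipationIndexes:
    def test_hypothesis1_neuron_significant(self, info_session_h1):
        s = info_session_h1
        s.sign_S = 1
        idx = ik.anticipation_indexes(s, n_perms=500, seed=0)
        s.sign_S = None
        assert idx.cue_index > 0 and idx.p_cue < 0.05
        assert idx.outcome_index > 0 and idx.p_outcome < 0.05

    def test_hypothesis2_cue_index_not_significant(self, attracted_gaze):
        n_sig = 0
        for seed in range(10):
            s = ik.gen_info_session(ik.info_neuron_spec(hypothesis=2),
                                    attracted_gaze, 30, seed=300 + seed)
            s.sign_S = 1
            idx = ik.anticipation_indexes(s, n_perms=200, seed=seed)
            n_sig += idx.p_cue < 0.05
        assert n_sig <= 2  # alpha = 0.05: not significant in >= 90% of runs

    def test_deterministic_given_seed(self, info_session_h1):
        s = info_session_h1
        s.sign_S = 1
        a = ik.anticipation_indexes(s, n_perms=150, seed=7)
        b = ik.anticipation_indexes(s, n_perms=150, seed=7)
        s.sign_S = None
        assert (a.p_cue, a.p_outcome) == (b.p_cue, b.p_outcome)

    def test_too_few_perms_rejected(self, info_session_h1):
        s = info_session_h1
        s.sign_S = 1
        with pytest.raises(ValidationError, match="n_perms"):
            ik.anticipation_indexes(s, n_perms=50)
        s.sign_S = None


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

def _step_session(t_step=0.2, seed=9, high=60.0, n_per_cond=30):
    dur = STANDARD_T_OUTCOME + 0.2
    nb = int(round(dur / PROFILE_BIN_S))
    profiles = {}
    for c in uncertainty_conditions():
        p = np.full(nb, 5.0)
        if c.uncertain:
            p[int(round(t_step / PROFILE_BIN_S)):] = high
        profiles[c] = p
    spec = NeuronSpec(base_profiles=profiles)
    s = ik.gen_uncertainty_session(spec, GazeBehaviorSpec(), n_per_cond,
                                   seed=seed)
    s.sign_S = 1
    return s


class TestDetectLatency:
    def test_step_neuron_latency_within_smoothing_delay(self):
        s = _step_session(t_step=0.2)
        res = ik.detect_latency(s, ik.normalize_activity(s))
        assert res.latency is not None
        assert 0.2 <= res.latency <= 0.24

    def test_flat_neuron_undetected(self, plain_gaze):
        spec = ik.uncertainty_neuron_spec(
            peak_rates={p: 8.0 for p in (0.0, 0.25, 0.5, 0.75, 1.0)},
            base_rate=8.0)
        s = ik.gen_uncertainty_session(spec, plain_gaze, 25, seed=400)
        s.sign_S = 1
        assert ik.detect_latency(s, ik.normalize_activity(s)).latency is None

    def test_info_task_uses_shorter_of_info_noinfo(self, info_session_h1):
        s = info_session_h1
        s.sign_S = 1
        res = ik.detect_latency(s, ik.normalize_activity(s),
                                use_zero_criterion=True)
        s.sign_S = None
        # signal ramps on Info trials during the CS: detected, and the
        # overall latency is the shorter (Info) one, well before cue onset
        assert res.latency is not None and res.latency < 1.0


class TestAreaLatencyCompare:
    def test_identical_sets_give_p_one(self):
        lat = np.linspace(0.1, 0.5, 20)
        a, b, p = ik.area_latency_compare(lat, lat, n_perms=300, seed=0)
        assert a == b
        assert p == pytest.approx(1.0)

    def test_trim_count_is_ceil_of_one_percent(self):
        lats = np.arange(50) / 100.0 + 0.1
        a, _, _ = ik.area_latency_compare(lats, lats + 1.0, n_perms=100,
                                          seed=0)
        # n = 50 -> trim 1 shortest -> min of the rest
        assert a == pytest.approx(lats[1])

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.3, 30)
        _, _, p = ik.area_latency_compare(a, a + 0.1, n_perms=2000, seed=1)
        assert p < 0.05


# ---------------------------------------------------------------------------
# Graded vs rough; inverted-U fit
# ---------------------------------------------------------------------------

class TestGradedVsRough:
    def test_parabolic_tuning_positive_both(self, std_session):
        s = std_session
        s.sign_S = 1
        rough, graded, p = ik.graded_vs_rough(s, ik.normalize_activity(s))
        s.sign_S = None
        assert rough > 0 and graded > 0 and p < 0.05

    def test_flat_top_tuning_graded_near_zero(self, plain_gaze):
        peaks = {0.0: 2.0, 0.25: 16.0, 0.5: 16.0, 0.75: 16.0, 1.0: 2.0}
        spec = ik.uncertainty_neuron_spec(peak_rates=peaks)
        s = ik.gen_uncertainty_session(spec, plain_gaze, 30, seed=105)
        s.sign_S = 1
        rough, graded, p = ik.graded_vs_rough(s, ik.normalize_activity(s))
        assert rough > 0
        assert abs(graded) < 0.2 and p > 0.05

    def test_population_binomial_example(self):
        # 31 of 32 significant neurons positive: exact binomial at 0.5
        from scipy.stats import binomtest
        assert binomtest(31, 32, 0.5).pvalue < 0.001


class TestFitInvertedU:
    probs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

    def test_exact_parabola_zero_residuals(self):
        y = -4 * (self.probs - 0.5) ** 2 + 1.5
        fit = ik.fit_inverted_u(self.probs, y, n_boot=0)
        yhat = np.polyval(fit["coef"], self.probs)
        assert np.allclose(yhat, y, atol=1e-10)

    def test_symmetric_inverted_u_vertex_at_half(self):
        rng = np.random.default_rng(0)
        base = -4 * (self.probs - 0.5) ** 2 + 1.0
        act = base + rng.normal(0, 0.01, size=(40, 5))
        fit = ik.fit_inverted_u(self.probs, act, n_boot=200, seed=0)
        assert fit["vertex"] == pytest.approx(0.5, abs=0.02)
        assert np.all(fit["se"] > 0)

    def test_linear_input_has_no_quadratic_term(self):
        fit = ik.fit_inverted_u(self.probs, 2.0 * self.probs + 1.0, n_boot=0)
        assert fit["coef"][0] == pytest.approx(0.0, abs=1e-10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValidationError):
            ik.fit_inverted_u([0.0, 1.0], [1.0, 2.0])


def test_causal_boxcar_matches_trailing_mean():
    x = np.arange(10.0)[None, :]
    out = _causal_boxcar(x, 3)
    assert out[0, 0] == 0.0
    assert out[0, 1] == 0.5
    assert out[0, 5] == pytest.approx(np.mean([3, 4, 5]))
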