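"""Spike-train normalization and uncertainty-signal statistics.

The central quantity is the *uncertainty signal* ``U``: the ROC area for
using a neuron's firing rate to distinguish trials with uncertain rewards
(0 < p < 1) from trials with certain rewards (p = 0 or 1).  ``U`` = 0.5 means
no discrimination; values above/below 0.5 mean uncertainty-excited/inhibited
firing.  Signals from neurons of either sign are pooled through the
normalized uncertainty signal::

    U_N = 0.5 + (U - 0.5) * S

where ``S`` in {-1, +1} is the neuron's sign of uncertainty coding.

Two anticipation indexes quantify whether a neuron's uncertainty signal
anticipates the *moment of gaining information*: the Informative Cue
Anticipation Index (Info minus Noinfo uncertainty signal in the 0.5 s pre-cue
window) and the Uncertain Outcome Anticipation Index (growth of the Noinfo
uncertainty signal from the post-cue window, 0.15-0.65 s after cue onset, to
the 0.5 s pre-outcome window).  Both are tested with trial-label permutation
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_session import (AnalysisWindow, NeuronSession, Trial,
                           ValidationError, window_slice)

__all__ = [
    "smooth_exponential",
    "NormalizedActivity",
    "normalize_activity",
    "roc_area",
    "rank_sum_p",
    "classify_uncertainty_neuron",
    "normalized_uncertainty_signal",
    "uncertainty_signal",
    "AnticipationIndexes",
    "anticipation_indexes",
    "anticipation_indexes_from_values",
    "LatencyResult",
    "detect_latency",
    "area_latency_compare",
    "graded_vs_rough",
    "fit_inverted_u",
    "window_rates",
]


# ---------------------------------------------------------------------------
# Smoothing and normalization
# ---------------------------------------------------------------------------

def smooth_exponential(spikes: np.ndarray, n_ms: int,
                       kernel_mean: float = 0.030) -> np.ndarray:
    """Smooth a spike train with a causal exponential kernel.

    The kernel ``k(t) = exp(-t / tau) / tau`` (zero for t < 0, mean ``tau`` =
    ``kernel_mean`` seconds) integrates to 1, so the output is an unbiased
    per-millisecond firing-rate estimate in spikes/s.
    """
    if kernel_mean <= 0:
        raise ValidationError("kernel_mean must be positive")
    spikes = np.asarray(spikes, dtype=float)
    counts = np.zeros(n_ms)
    ms = np.floor(spikes * 1000.0).astype(int)
    ms = ms[(ms >= 0) & (ms < n_ms)]
    np.add.at(counts, ms, 1.0)
    tau_ms = kernel_mean * 1000.0
    support = int(math.ceil(8.0 * tau_ms))
    k = np.exp(-np.arange(support) / tau_ms)
    k /= k.sum() * 0.001  # unit integral -> spikes/s
    return np.convolve(counts, k)[:n_ms]


@dataclass
class NormalizedActivity:
    """Per-millisecond z-scored, sign-normalized activity for every trial.

    ``traces[i, t]`` is trial ``i``'s normalized activity at millisecond
    ``t``: the exponentially smoothed rate minus ``mean``, divided by ``sd``,
    multiplied by ``sign_S``.  ``mean`` and ``sd`` are the moments of the
    concatenated per-condition average time courses, so a value of +1 means
    the firing rate deviated 1 SD from the neuron's average, in the direction
    of its uncertainty response.
    """

    traces: np.ndarray       # (n_trials, n_ms)
    mean: float
    sd: float
    sign_S: int
    kernel_mean: float

    def renormalize(self, rates: np.ndarray) -> np.ndarray:
        """Apply the stored transform to raw rates (exact reproduction)."""
        return (np.asarray(rates, dtype=float) - self.mean) / self.sd \
            * self.sign_S


def normalize_activity(session: NeuronSession,
                       kernel_mean: float = 0.030) -> NormalizedActivity:
    """Smooth, z-score, and sign-normalize a session's spiking activity.

    The z-transform is defined on the concatenation of the per-condition
    CS-aligned average time courses (one smoothed mean trace per condition),
    then applied to every single-trial smoothed rate, and finally multiplied
    by the neuron's sign of uncertainty coding.
    """
    if session.sign_S not in (-1, 1):
        raise ValidationError("sign_S must be set before normalization")
    n_ms = min(t.n_ms for t in session.trials)
    rates = np.stack([smooth_exponential(t.spikes, n_ms, kernel_mean)
                      for t in session.trials])
    cond_means = []
    conds = session.conditions()
    cond_of = [t.condition for t in session.trials]
    for c in conds:
        idx = [i for i, cc in enumerate(cond_of) if cc == c]
        cond_means.append(rates[idx].mean(axis=0))
    concat = np.concatenate(cond_means)
    mean = float(concat.mean())
    sd = float(concat.std(ddof=0))
    if sd == 0.0:
        raise ValidationError("constant neuron: zero SD in normalization")
    traces = (rates - mean) / sd * session.sign_S
    return NormalizedActivity(traces=traces, mean=mean, sd=sd,
                              sign_S=session.sign_S,
                              kernel_mean=kernel_mean)


# ---------------------------------------------------------------------------
# ROC area and rank-sum p-values
# ---------------------------------------------------------------------------

def roc_area(uncertain_rates: Sequence, certain_rates: Sequence) -> float:
    """ROC area for distinguishing uncertain-trial from certain-trial rates.

    Equals the Mann-Whitney U statistic divided by ``n1 * n2`` with ties
    counting one half: the probability that a random uncertain-trial value
    exceeds a random certain-trial value (+ half the tie probability).
    """
    x = np.asarray(uncertain_rates, dtype=float)
    y = np.asarray(certain_rates, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("roc_area requires two non-empty samples")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    return float(u1 / (x.size * y.size))


def rank_sum_p(x: Sequence, y: Sequence) -> float:
    """Two-sided Mann-Whitney p-value, normal approximation with tie
    correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def _mwu_columns(x: np.ndarray, y: np.ndarray) -> tuple:
    """Column-wise Mann-Whitney AUC and two-sided normal-approximation
    p-value with tie correction.

    ``x`` is ``(n1, T)`` and ``y`` ``(n2, T)``; returns ``(auc, p)`` each of
    shape ``(T,)``.
    """
    n1, n2 = x.shape[0], y.shape[0]
    data = np.vstack([x, y])
    ranks = stats.rankdata(data, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n2)
    n = n1 + n2
    # tie term sum(t^3 - t) per column
    d = np.sort(data, axis=0)
    tie = np.zeros(data.shape[1])
    for j in range(data.shape[1]):
        _, cnt = np.unique(d[:, j], return_counts=True)
        tie[j] = (cnt ** 3 - cnt).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    var = np.maximum(var, 1e-300)
    num = u1 - n1 * n2 / 2.0
    num = num - 0.5 * np.sign(num)  # continuity correction
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 1e-299] = 1.0
    return auc, p


# ---------------------------------------------------------------------------
# Window rates and inclusion/sign classification
# ---------------------------------------------------------------------------

def window_rates(trials: Sequence[Trial], window: AnalysisWindow) -> np.ndarray:
    """Per-trial firing rate (spikes/s) from unsmoothed counts in a window."""
    width = window.t_end - window.t_start
    if width <= 0:
        raise ValidationError("window_rates needs a non-empty window")
    return np.array([window_slice(t, window).spikes.size / width
                     for t in trials])


def _split_uncertain(trials: Sequence[Trial]) -> tuple:
    unc = [t for t in trials if t.condition.uncertain]
    cert = [t for t in trials if not t.condition.uncertain]
    return unc, cert


def classify_uncertainty_neuron(session: NeuronSession,
                                alpha: float = 0.05) -> tuple:
    """Inclusion test and sign of uncertainty coding for one neuron.

    Standard uncertainty tasks: firing in [0.1, 2.5) s after CS onset on
    uncertain-reward trials must differ from *both* the 0% and the 100%
    reward trials (rank-sum tests, both p < alpha, differences of the same
    sign).  Information tasks: firing in the 0.5 s pre-outcome window on
    Noinfo trials must discriminate certain from uncertain reward (rank-sum
    p < alpha).  The sign is +1 if the uncertain-vs-certain ROC area exceeds
    0.5, else -1.

    Returns ``(included, sign_S)``; the session is not modified.
    """
    task = session.task_id
    if task is None:
        raise ValidationError("empty session")
    if task == "standard_uncertainty":
        w = AnalysisWindow(0.1, 2.5, "cs_on")
        unc, cert = _split_uncertain(session.trials)
        zero = [t for t in cert if t.condition.reward_prob == 0.0]
        full = [t for t in cert if t.condition.reward_prob == 1.0]
        if not unc or not zero or not full:
            raise ValidationError("need uncertain, 0%, and 100% conditions")
        r_unc = window_rates(unc, w)
        r0 = window_rates(zero, w)
        r1 = window_rates(full, w)
        p0 = rank_sum_p(r_unc, r0)
        p1 = rank_sum_p(r_unc, r1)
        d0 = r_unc.mean() - r0.mean()
        d1 = r_unc.mean() - r1.mean()
        included = (p0 < alpha) and (p1 < alpha) and (d0 * d1 > 0)
        r_cert = window_rates(cert, w)
        sign = 1 if roc_area(r_unc, r_cert) > 0.5 else -1
        return included, sign
    # information tasks: Noinfo certain vs uncertain, 0.5 s before outcome
    noinfo = session.trials_where(cs_kind="noinfo")
    unc, cert = _split_uncertain(noinfo)
    if not unc or not cert:
        raise ValidationError("need uncertain and certain Noinfo conditions")
    t_out = noinfo[0].t_outcome
    w = AnalysisWindow(t_out - 0.5, t_out, "cs_on")
    r_unc = window_rates(unc, w)
    r_cert = window_rates(cert, w)
    p = rank_sum_p(r_unc, r_cert)
    sign = 1 if roc_area(r_unc, r_cert) > 0.5 else -1
    return p < alpha, sign


def normalized_uncertainty_signal(U: float, sign_S: int) -> float:
    """``U_N = 0.5 + (U - 0.5) * S``: flip inhibited neurons' signals so the
    population can be pooled."""
    return 0.5 + (U - 0.5) * sign_S


def uncertainty_signal(session: NeuronSession, window: AnalysisWindow,
                       split: str = "pooled") -> float:
    """ROC-area uncertainty signal in a window.

    ``split`` restricts to Info or Noinfo trials in information tasks
    (``"pooled"`` uses all trials).
    """
    trials = session.trials
    if split in ("info", "noinfo"):
        trials = [t for t in trials if t.condition.cs_kind == split]
    elif split != "pooled":
        raise ValidationError(f"unknown split {split!r}")
    unc, cert = _split_uncertain(trials)
    return roc_area(window_rates(unc, window), window_rates(cert, window))


# ---------------------------------------------------------------------------
# Anticipation indexes
# ---------------------------------------------------------------------------

@dataclass
class AnticipationIndexes:
    """Informative Cue and Uncertain Outcome Anticipation Indexes.

    ``cue_index`` = Info minus Noinfo normalized uncertainty signal in the
    0.5 s pre-cue window; ``outcome_index`` = Noinfo pre-outcome minus
    post-cue normalized uncertainty signal.  ``p_cue`` / ``p_outcome`` are
    two-tailed permutation p-values (Info/Noinfo labels shuffled, and window
    labels swapped per trial, respectively).
    """

    cue_index: float
    outcome_index: float
    p_cue: float
    p_outcome: float
    n_perms: int


def _index_pair(v_precue, v_postcue, v_preout, info, unc, sign) -> tuple:
    def u_n(vals, mask):
        return normalized_uncertainty_signal(
            roc_area(vals[mask & unc], vals[mask & ~unc]), sign)
    cue = u_n(v_precue, info) - u_n(v_precue, ~info)
    outc = u_n(v_preout, ~info) - u_n(v_postcue, ~info)
    return cue, outc


def anticipation_indexes_from_values(v_precue: np.ndarray,
                                     v_postcue: np.ndarray,
                                     v_preout: np.ndarray,
                                     info: np.ndarray,
                                     uncertain: np.ndarray,
                                     reward_prob: np.ndarray,
                                     sign_S: int = 1,
                                     n_perms: int = 20000,
                                     seed: Optional[int] = None
                                     ) -> AnticipationIndexes:
    """Anticipation indexes from per-trial window values.

    Used both for neural rates and for behavioral gaze flags (the value at
    the last millisecond of each window).  The cue-index permutation shuffles
    Info/Noinfo labels within each reward-probability level; the
    outcome-index permutation swaps each Noinfo trial's post-cue/pre-outcome
    value pair independently.
    """
    if n_perms < 100:
        raise ValidationError("n_perms < 100 gives unstable p-values")
    v_precue = np.asarray(v_precue, dtype=float)
    v_postcue = np.asarray(v_postcue, dtype=float)
    v_preout = np.asarray(v_preout, dtype=float)
    info = np.asarray(info, dtype=bool)
    unc = np.asarray(uncertain, dtype=bool)
    prob = np.asarray(reward_prob, dtype=float)
    cue_true, out_true = _index_pair(v_precue, v_postcue, v_preout,
                                     info, unc, sign_S)
    rng = np.random.default_rng(seed)
    prob_groups = [np.flatnonzero(prob == p) for p in np.unique(prob)]
    noinfo_idx = np.flatnonzero(~info)
    n_cue_ge = 0
    n_out_ge = 0
    for _ in range(n_perms):
        perm_info = info.copy()
        for idx in prob_groups:
            perm_info[idx] = info[idx[rng.permutation(idx.size)]]
        cue_p, _ = _index_pair(v_precue, v_postcue, v_preout,
                               perm_info, unc, sign_S)
        if abs(cue_p) >= abs(cue_true) - 1e-12:
            n_cue_ge += 1
        swap = rng.random(noinfo_idx.size) < 0.5
        post = v_postcue.copy()
        pre = v_preout.copy()
        sw = noinfo_idx[swap]
        post[sw], pre[sw] = v_preout[sw], v_postcue[sw]
        _, out_p = _index_pair(v_precue, post, pre, info, unc, sign_S)
        if abs(out_p) >= abs(out_true) - 1e-12:
            n_out_ge += 1
    return AnticipationIndexes(
        cue_index=cue_true, outcome_index=out_true,
        p_cue=(1.0 + n_cue_ge) / (n_perms + 1.0),
        p_outcome=(1.0 + n_out_ge) / (n_perms + 1.0),
        n_perms=n_perms,
    )


def anticipation_indexes(session: NeuronSession, n_perms: int = 20000,
                         seed: Optional[int] = None) -> AnticipationIndexes:
    """Neural anticipation indexes for an information-task session.

    Window values are unsmoothed per-trial firing rates in the 0.5 s pre-cue
    window, the post-cue window [0.15, 0.65) s after cue onset, and the 0.5 s
    pre-outcome window.
    """
    if session.task_id == "standard_uncertainty":
        raise ValidationError("anticipation indexes need an information task")
    if session.sign_S not in (-1, 1):
        raise ValidationError("sign_S must be set")
    trials = session.trials
    t_cue = trials[0].t_cue_on
    t_out = trials[0].t_outcome
    w_precue = AnalysisWindow(t_cue - 0.5, t_cue, "cs_on")
    w_postcue = AnalysisWindow(t_cue + 0.15, t_cue + 0.65, "cs_on")
    w_preout = AnalysisWindow(t_out - 0.5, t_out, "cs_on")
    return anticipation_indexes_from_values(
        window_rates(trials, w_precue),
        window_rates(trials, w_postcue),
        window_rates(trials, w_preout),
        info=np.array([t.condition.cs_kind == "info" for t in trials]),
        uncertain=np.array([t.condition.uncertain for t in trials]),
        reward_prob=np.array([t.condition.reward_prob for t in trials]),
        sign_S=session.sign_S, n_perms=n_perms, seed=seed,
    )


# ---------------------------------------------------------------------------
# Latency of uncertainty coding
# ---------------------------------------------------------------------------

@dataclass
class LatencyResult:
    """Latency at which a neuron's uncertainty coding becomes reliable."""

    latency: Optional[float]     # s after CS onset, or None if undetected
    auc_zero: Optional[np.ndarray] = None
    auc_full: Optional[np.ndarray] = None


def _causal_boxcar(traces: np.ndarray, width_ms: int) -> np.ndarray:
    """Causal boxcar mean over the trailing ``width_ms`` samples (partial
    means at the start)."""
    cs = np.cumsum(traces, axis=-1)
    out = np.empty_like(traces)
    w = width_ms
    out[..., :w] = cs[..., :w] / np.arange(1, w + 1)
    out[..., w:] = (cs[..., w:] - cs[..., :-w]) / w
    return out


def detect_latency(session: NeuronSession, activity,
                   alpha: float = 0.005, consec_ms: int = 24,
                   start_ms: int = 50, boxcar_ms: int = 101,
                   use_zero_criterion: bool = True) -> LatencyResult:
    """Latency of uncertainty coding for one neuron.

    Normalized activity is further smoothed with a causal 101 ms boxcar;
    from 50 ms after CS onset, each millisecond is tested for (1) uncertain
    vs 0% reward ROC with p < 0.005, (2) uncertain vs 100% reward ROC with
    p < 0.005, (3) both ROC areas on the same side of 0.5.  The latency is
    the first millisecond where the criteria hold for at least 24 consecutive
    milliseconds; in information tasks the Info and Noinfo latencies are
    computed separately and the shorter one is reported.  Task variants
    without a 0% condition drop criterion (1) (``use_zero_criterion=False``).
    """
    smoothed = _causal_boxcar(activity.traces, boxcar_ms)

    def _one(trials_idx: np.ndarray) -> Optional[int]:
        conds = [session.trials[i].condition for i in trials_idx]
        unc = np.array([c.uncertain for c in conds])
        p0_idx = np.array([c.reward_prob == 0.0 for c in conds])
        p1_idx = np.array([c.reward_prob == 1.0 for c in conds])
        tr = smoothed[trials_idx]
        x = tr[unc][:, start_ms:]
        ok = np.ones(x.shape[1], dtype=bool)
        sign_ref = None
        if use_zero_criterion:
            if not p0_idx.any():
                raise ValidationError("no 0% condition present")
            auc0, p0 = _mwu_columns(x, tr[p0_idx][:, start_ms:])
            ok &= p0 < alpha
            sign_ref = auc0 > 0.5
        if not p1_idx.any():
            raise ValidationError("no 100% condition present")
        auc1, p1 = _mwu_columns(x, tr[p1_idx][:, start_ms:])
        ok &= p1 < alpha
        if sign_ref is not None:
            ok &= (auc1 > 0.5) == sign_ref
        # first index with >= consec_ms consecutive True
        run = 0
        for t in range(ok.size):
            run = run + 1 if ok[t] else 0
            if run >= consec_ms:
                return start_ms + t - consec_ms + 1
        return None

    if session.task_id == "standard_uncertainty":
        lat_ms = _one(np.arange(len(session.trials)))
    else:
        lats = []
        for kind in ("info", "noinfo"):
            idx = np.array([i for i, t in enumerate(session.trials)
                            if t.condition.cs_kind == kind])
            if idx.size:
                lat = _one(idx)
                if lat is not None:
                    lats.append(lat)
        lat_ms = min(lats) if lats else None
    return LatencyResult(latency=None if lat_ms is None else lat_ms / 1000.0)


def area_latency_compare(latencies_a: Sequence, latencies_b: Sequence,
                         n_perms: int = 20000,
                         seed: Optional[int] = None,
                         trim_frac: float = 0.01) -> tuple:
    """Compare two areas' population latencies.

    Each area's latency is the minimum single-neuron latency after trimming
    the shortest ``ceil(trim_frac * n)`` latencies (robustness to false
    positives).  The p-value permutes the assignment of neurons to areas.
    Returns ``(latency_a, latency_b, p)``.
    """
    a = np.sort(np.asarray(latencies_a, dtype=float))
    b = np.sort(np.asarray(latencies_b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 detected latencies per area")

    def _area_latency(v: np.ndarray) -> float:
        k = int(math.ceil(trim_frac * v.size))
        v = np.sort(v)
        return float(v[min(k, v.size - 1)])

    stat_true = _area_latency(a) - _area_latency(b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perms):
        perm = rng.permutation(pooled.size)
        pa = pooled[perm[: a.size]]
        pb = pooled[perm[a.size:]]
        if abs(_area_latency(pa) - _area_latency(pb)) >= abs(stat_true) - 1e-12:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perms + 1.0)
    return _area_latency(a), _area_latency(b), p


# ---------------------------------------------------------------------------
# Rough vs graded uncertainty coding; inverted-U fit
# ---------------------------------------------------------------------------

def graded_vs_rough(session: NeuronSession, activity,
                    window: Optional[AnalysisWindow] = None) -> tuple:
    """Rough and graded uncertainty coding of a 5-probability session.

    *Rough* coding is the difference in mean normalized activity between the
    pooled uncertain CSs (25/50/75%) and the pooled certain CSs (0/100%);
    *graded* coding is the difference between the maximally uncertain 50% CS
    and the intermediately uncertain 25/75% CSs.  ``p_graded`` is a rank-sum
    test on the trial-level values.  The default window is the 0.5 s
    pre-outcome window.

    Returns ``(rough, graded, p_graded)`` in normalized (z) units.
    """
    probs = {t.condition.reward_prob for t in session.trials}
    if not {0.0, 0.25, 0.5, 0.75, 1.0} <= probs:
        raise ValidationError("need the 5-probability standard task")
    if window is None:
        t_out = session.trials[0].t_outcome
        window = AnalysisWindow(t_out - 0.5, t_out, "cs_on")
    ms0 = int(round(window.t_start * 1000))
    ms1 = int(round(window.t_end * 1000))
    vals = activity.traces[:, ms0:ms1].mean(axis=1)
    prob = np.array([t.condition.reward_prob for t in session.trials])
    unc = (prob > 0) & (prob < 1)
    rough = float(vals[unc].mean() - vals[~unc].mean())
    mid = (prob == 0.25) | (prob == 0.75)
    high = prob == 0.5
    graded = float(vals[high].mean() - vals[mid].mean())
    p = rank_sum_p(vals[high], vals[mid])
    return rough, graded, p


def fit_inverted_u(probabilities: Sequence, activity: np.ndarray,
                   n_boot: int = 1000,
                   seed: Optional[int] = None) -> dict:
    """Second-order polynomial fit of activity against reward probability.

    ``activity`` is ``(n_neurons, n_probs)`` mean normalized activity (a
    single 1-D profile is also accepted).  The quadratic is fitted to the
    across-neuron mean profile by least squares; coefficient standard errors
    come from a bootstrap over neurons.  Returns ``{"coef": (c2, c1, c0),
    "se": ..., "vertex": -c1 / (2 c2)}``.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.unique(p).size < 3:
        raise ValidationError("need >= 3 distinct probability levels")
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    if act.shape[1] != p.size:
        raise ValidationError("activity and probabilities disagree on levels")
    mean_prof = act.mean(axis=0)
    coef = np.polyfit(p, mean_prof, 2)
    if act.shape[0] > 1 and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 3))
        for b in range(n_boot):
            idx = rng.integers(0, act.shape[0], act.shape[0])
            boots[b] = np.polyfit(p, act[idx].mean(axis=0), 2)
        se = boots.std(axis=0, ddof=1)
    else:
        se = np.full(3, np.nan)
    vertex = float(-coef[1] / (2.0 * coef[0])) if coef[0] != 0 else math.nan
    return {"coef": coef, "se": se, "vertex": vertex}
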