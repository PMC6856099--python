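"""Maximum-likelihood model of gaze-modulated firing.

The model explains a neuron's binned firing rate on trial ``tr`` in time bin
``t`` of condition ``c`` as::

    Rate(tr, t) = beta(c, t) * (1 + GazeMod(tr, t) * w_gain)
                  + GazeMod(tr, t) * w_offset + eps

where ``GazeMod`` is the trial's binary gaze-on-stimulus trace convolved with
a Gaussian kernel of mean ``mu`` and SD ``sigma`` (both in seconds) and
averaged within each 50 ms bin, ``w_gain`` is a multiplicative gain on the
condition response profile ``beta``, ``w_offset`` an additive rate change,
and ``eps`` homoscedastic Gaussian noise.

Sign convention: positive ``mu`` means the neural modulation *leads* the gaze
change ("neurons first"); around an isolated gaze shift onto the stimulus the
modulation time course is the cumulative Gaussian ``Phi((t + mu) / sigma)``.

``beta`` and the noise variance enter the Gaussian likelihood quadratically
and are profiled out in closed form, leaving a 4-parameter bounded search
over ``(mu, sigma, w_gain, w_offset)`` solved with the Trust Region
Reflective algorithm.  Significance of the gaze terms is assessed by refitting
on surrogate data sets in which gaze traces are shuffled among trials of the
same condition (a one-tailed permutation test: shuffling cannot, in
expectation, improve the fit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import norm

from .core_session import NeuronSession, ValidationError

__all__ = [
    "gazemod",
    "GazeModDesign",
    "design_from_session",
    "GazeModelFit",
    "fit_gaze_model",
    "gaze_model_significance",
    "GazeModTimecourse",
    "modulation_timecourse_and_latency",
    "pool_tasks",
]


# ---------------------------------------------------------------------------
# GazeMod: Gaussian-kernel temporal coupling between gaze and firing
# ---------------------------------------------------------------------------

def _kernel(mu: float, sigma: float, dt: float) -> tuple:
    """Discrete Gaussian kernel sampled every ``dt`` seconds.

    Returns ``(lo, weights)`` where the weight ``weights[j]`` applies to lag
    ``(lo + j) * dt`` seconds.  Support is ``mu +/- 4 sigma`` (at least one
    sample step), renormalized to sum to 1; ``sigma = 0`` degenerates to a
    single tap at the sample nearest ``mu``.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    half = max(4.0 * sigma, dt)
    lo = int(math.floor((mu - half) / dt))
    hi = int(math.ceil((mu + half) / dt))
    taus = np.arange(lo, hi + 1) * dt
    if sigma == 0.0:
        w = np.zeros(taus.size)
        w[np.argmin(np.abs(taus - mu))] = 1.0
    else:
        w = np.exp(-0.5 * ((taus - mu) / sigma) ** 2)
        tot = w.sum()
        if tot <= 0.0:  # sigma far below the sample step: degenerate tap
            w = np.zeros(taus.size)
            w[np.argmin(np.abs(taus - mu))] = 1.0
        else:
            w /= tot
    return lo, w


def _correlate_rows(g: np.ndarray, lo: int, w: np.ndarray) -> np.ndarray:
    """out[..., t] = sum_j w[j] * g[..., t + lo + j], edges padded with the
    boundary value."""
    L = w.size
    hi = lo + L - 1
    pad_l = max(0, -lo)
    pad_r = max(0, hi)
    pad = [(0, 0)] * (g.ndim - 1) + [(pad_l, pad_r)]
    gp = np.pad(g, pad, mode="edge")
    start = pad_l + lo
    # correlation via convolution with the reversed kernel
    out = np.apply_along_axis(
        lambda row: np.convolve(row, w[::-1], mode="valid"), -1, gp
    ) if g.ndim > 1 else np.convolve(gp, w[::-1], mode="valid")
    n = g.shape[-1]
    return out[..., start:start + n]


def gazemod(gaze_flags: np.ndarray, mu: float, sigma: float,
            dt: float = 0.001) -> np.ndarray:
    """Convolve a binary gaze trace with a Gaussian kernel.

    Parameters
    ----------
    gaze_flags:
        0/1 gaze-on-stimulus flags sampled every ``dt`` seconds; 1-D (one
        trial) or 2-D ``(n_trials, n_samples)``.
    mu, sigma:
        Kernel mean and SD in seconds.  Positive ``mu`` makes the modulation
        lead the gaze change.
    dt:
        Sampling interval in seconds (1 ms by default).

    Returns
    -------
    Array of the same shape with values in [0, 1]; edges are padded with the
    boundary gaze value, so a constant trace maps to itself.
    """
    g = np.asarray(gaze_flags, dtype=float)
    lo, w = _kernel(mu, sigma, dt)
    return _correlate_rows(g, lo, w)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class GazeModDesign:
    """Binned firing rates plus gaze traces, ready for model fitting.

    ``rates`` is ``(n_trials, n_bins)`` in spikes/s (spike count in the bin
    divided by the bin width), the bin grid spans ``[0.2 s post-CS, 0.1 s
    post-outcome)`` in 50 ms steps, and ``gaze`` holds the per-trial gaze
    flags at ``gaze_dt`` resolution over the same span.
    """

    rates: np.ndarray            # (n_trials, n_bins) spikes/s
    gaze: np.ndarray             # (n_trials, n_samples) 0/1 at gaze_dt
    condition_ids: np.ndarray    # (n_trials,) small ints
    bin_s: float = 0.05
    gaze_dt: float = 0.010
    t_start: float = 0.2

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        self.condition_ids = np.asarray(self.condition_ids)
        if self.rates.shape[0] != self.gaze.shape[0]:
            raise ValidationError("rates and gaze disagree on trial count")
        if self.condition_ids.shape[0] != self.rates.shape[0]:
            raise ValidationError("condition_ids disagree on trial count")
        per_bin = int(round(self.bin_s / self.gaze_dt))
        if self.gaze.shape[1] < self.rates.shape[1] * per_bin:
            raise ValidationError("gaze trace shorter than the bin grid")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def gazemod_bins(self, mu: float, sigma: float) -> np.ndarray:
        """Per-trial GazeMod averaged within each 50 ms bin."""
        gm = gazemod(self.gaze, mu, sigma, dt=self.gaze_dt)
        per_bin = int(round(self.bin_s / self.gaze_dt))
        n = self.n_bins * per_bin
        return gm[:, :n].reshape(self.n_trials, self.n_bins, per_bin).mean(2)

    def shuffled(self, rng: np.random.Generator) -> "GazeModDesign":
        """Copy with gaze traces shuffled among trials of the same condition."""
        perm = np.arange(self.n_trials)
        for c in np.unique(self.condition_ids):
            idx = np.flatnonzero(self.condition_ids == c)
            perm[idx] = idx[rng.permutation(idx.size)]
        return GazeModDesign(
            rates=self.rates, gaze=self.gaze[perm],
            condition_ids=self.condition_ids, bin_s=self.bin_s,
            gaze_dt=self.gaze_dt, t_start=self.t_start,
        )


def design_from_session(session: NeuronSession, bin_s: float = 0.05,
                        gaze_dt: float = 0.010,
                        gaze_radius: float = 3.0,
                        centers: Optional[dict] = None) -> GazeModDesign:
    """Build a :class:`GazeModDesign` from a session.

    The bin grid spans 0.2 s after CS onset to 0.1 s after outcome delivery
    (all trials must share the outcome time).  Gaze is flagged "on" when the
    eye is within ``gaze_radius`` degrees of the CS center; ``centers`` may
    map ``cs_location`` to a calibrated ``(x, y)`` window center (defaults to
    the nominal stimulus centers).
    """
    from .gaze_events import NOMINAL_CENTERS, gaze_on_flags

    if not session.trials:
        raise ValidationError("session has no trials")
    t_out = {t.t_outcome for t in session.trials}
    if len(t_out) != 1:
        raise ValidationError("trials disagree on outcome time")
    t_end = t_out.pop() + 0.1
    t_start = 0.2
    n_bins = int(round((t_end - t_start) / bin_s))
    conds = session.conditions()
    cond_index = {c: i for i, c in enumerate(conds)}

    step = int(round(gaze_dt * 1000))
    n_gaze = int(round((t_end - t_start) / gaze_dt))
    rates = np.empty((len(session.trials), n_bins))
    gaze = np.empty((len(session.trials), n_gaze))
    cond_ids = np.empty(len(session.trials), dtype=int)
    edges = t_start + bin_s * np.arange(n_bins + 1)
    for i, tr in enumerate(session.trials):
        counts, _ = np.histogram(tr.spikes, bins=edges)
        rates[i] = counts / bin_s
        center = (centers or {}).get(tr.condition.cs_location,
                                     NOMINAL_CENTERS[tr.condition.cs_location])
        flags = gaze_on_flags(tr, center, radius=gaze_radius)
        ms0 = int(round(t_start * 1000))
        need = ms0 + n_gaze * step
        if flags.size < need:
            flags = np.pad(flags, (0, need - flags.size), mode="edge")
        gaze[i] = flags[ms0:need].reshape(n_gaze, step).mean(1) >= 0.5
        cond_ids[i] = cond_index[tr.condition]
    return GazeModDesign(rates=rates, gaze=gaze, condition_ids=cond_ids,
                         bin_s=bin_s, gaze_dt=gaze_dt, t_start=t_start)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class GazeModelFit:
    """Fitted gaze-modulation model for one neuron in one task."""

    beta: np.ndarray             # (n_conditions, n_bins) spikes/s
    mu: float                    # s, in [-1, 1]
    sigma: float                 # s, in [0, 1]
    w_gain: float                # dimensionless
    w_offset: float              # spikes/s
    logL: float
    converged: bool
    n_obs: int
    p_perm: Optional[float] = None
    n_perms: int = 0
    latency_mod: Optional[float] = None

    @property
    def gain_log2(self) -> float:
        """Fitted gain expressed in log2 units (0 = no change, +1 = doubled)."""
        return float(np.log2(max(1.0 + self.w_gain, 2.0 ** -6)))


def _profile(design: GazeModDesign, theta: np.ndarray):
    """Closed-form beta and residuals given (mu, sigma, w_gain, w_offset)."""
    mu, sigma, wg, wo = theta
    g = design.gazemod_bins(mu, sigma)
    a = 1.0 + g * wg
    y = design.rates - g * wo
    n_cond = int(design.condition_ids.max()) + 1
    beta = np.zeros((n_cond, design.n_bins))
    resid = np.empty_like(design.rates)
    for c in range(n_cond):
        idx = design.condition_ids == c
        if not np.any(idx):
            continue
        ac, yc = a[idx], y[idx]
        den = (ac * ac).sum(0)
        num = (ac * yc).sum(0)
        bc = num / np.maximum(den, 1e-12)
        beta[c] = bc
        resid[idx] = yc - ac * bc
    return beta, resid


def _neg_logl(resid: np.ndarray) -> float:
    n = resid.size
    sse = float((resid * resid).sum())
    sigma2 = max(sse / n, 1e-300)
    return 0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_gaze_model(design: GazeModDesign, max_fevals: int = 100,
                   x0: Optional[Sequence] = None) -> GazeModelFit:
    """Fit the gaze-modulation model by maximum likelihood.

    The condition/bin response profile ``beta`` and the Gaussian noise
    variance are profiled out analytically; the remaining bounded
    4-dimensional problem over ``(mu, sigma, w_gain, w_offset)`` is solved
    with the Trust Region Reflective algorithm
    (:func:`scipy.optimize.least_squares`, ``method='trf'``) started from
    ``(0, 0.1, 0, 0)`` and capped at ``max_fevals`` function evaluations.
    """
    counts = np.bincount(design.condition_ids)
    if np.any(counts[counts > 0] < 2):
        warnings.warn("fewer than 2 trials in some condition; "
                      "gaze-model fit may be poorly constrained")

    start = np.array([0.0, 0.1, 0.0, 0.0]) if x0 is None else np.asarray(
        x0, dtype=float)

    def residfun(theta):
        _, resid = _profile(design, theta)
        return resid.ravel()

    lb = np.array([-1.0, 0.0, -np.inf, -np.inf])
    ub = np.array([1.0, 1.0, np.inf, np.inf])
    start = np.clip(start, lb + 1e-9, ub - 1e-9)
    converged = True
    try:
        res = optimize.least_squares(
            residfun, start, bounds=(lb, ub), method="trf",
            max_nfev=max_fevals, diff_step=1e-3,
            ftol=1e-6, xtol=1e-6, gtol=1e-8,
        )
        theta = res.x
        converged = bool(res.status > 0)
    except Exception:
        theta = start
        converged = False

    # safeguard: never report a fit worse than the initial parameters
    beta, resid = _profile(design, theta)
    nll = _neg_logl(resid)
    beta0, resid0 = _profile(design, start)
    nll0 = _neg_logl(resid0)
    if nll0 < nll:
        theta, beta, nll = start, beta0, nll0
        converged = False

    return GazeModelFit(
        beta=beta, mu=float(theta[0]), sigma=float(theta[1]),
        w_gain=float(theta[2]), w_offset=float(theta[3]),
        logL=-nll, converged=converged, n_obs=design.rates.size,
    )


def gaze_model_significance(design: GazeModDesign, fit: GazeModelFit,
                            n_perms: int = 200,
                            seed: Optional[int] = None,
                            max_fevals: int = 100) -> tuple:
    """One-tailed permutation test of the gaze terms.

    Gaze traces are shuffled among trials sharing a condition and the model is
    refitted on each surrogate (warm-started at the true-fit parameters).
    Returns ``(p_perm, significant)`` where
    ``p = (1 + #{perm logL >= true logL}) / (n_perms + 1)`` and the neuron is
    called significant when the true log likelihood exceeds at least a
    191/200 fraction of the permuted ones (equivalently ``p <= 0.05``).
    """
    if n_perms < 20:
        raise ValidationError("n_perms must be >= 20")
    rng = np.random.default_rng(seed)
    warm = (fit.mu, fit.sigma, fit.w_gain, fit.w_offset)
    n_ge = 0
    for _ in range(n_perms):
        sfit = fit_gaze_model(design.shuffled(rng), max_fevals=max_fevals,
                              x0=warm)
        if sfit.logL >= fit.logL:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perms + 1.0)
    significant = (n_perms - n_ge) >= math.ceil(n_perms * 191.0 / 200.0)
    return p, significant


# ---------------------------------------------------------------------------
# Modulation time course and latency
# ---------------------------------------------------------------------------

@dataclass
class GazeModTimecourse:
    """Idealized GazeMod around an isolated gaze shift onto the stimulus."""

    times: np.ndarray            # s relative to the shift
    values: np.ndarray           # GazeMod in [0, 1]
    latency: float               # s at the 10%-of-maximum criterion


def modulation_timecourse_and_latency(fit: GazeModelFit,
                                      t_range: float = 1.0,
                                      criterion: float = 0.1
                                      ) -> GazeModTimecourse:
    """Time course of gaze-modulation around an idealized isolated shift.

    For a unit step in gaze at time 0 the modulation is the cumulative
    Gaussian ``Phi((t + mu) / sigma)``; the latency is where it reaches
    ``criterion`` (10% by default) of its maximum, in closed form
    ``Phi^-1(criterion) * sigma - mu`` (negative latency = modulation before
    the gaze shift).
    """
    if fit.w_gain == 0.0 and fit.w_offset == 0.0:
        raise ValidationError("zero modulation: latency undefined")
    times = np.arange(-t_range, t_range + 1e-12, 0.001)
    if fit.sigma == 0.0:
        values = (times + fit.mu >= 0).astype(float)
        latency = -fit.mu
    else:
        values = norm.cdf((times + fit.mu) / fit.sigma)
        latency = float(ndtri(criterion) * fit.sigma - fit.mu)
    return GazeModTimecourse(times=times, values=values, latency=latency)


def pool_tasks(fits: Sequence[GazeModelFit]) -> dict:
    """Combine per-task fits of one neuron.

    The total log likelihood is the sum over tasks; the gain, time course
    parameters, and modulation latency are averaged over tasks.
    """
    if not fits:
        raise ValidationError("need at least one fit to pool")
    lat = []
    for f in fits:
        if f.w_gain != 0.0 or f.w_offset != 0.0:
            lat.append(modulation_timecourse_and_latency(f).latency)
    return {
        "logL": float(sum(f.logL for f in fits)),
        "w_gain": float(np.mean([f.w_gain for f in fits])),
        "w_offset": float(np.mean([f.w_offset for f in fits])),
        "mu": float(np.mean([f.mu for f in fits])),
        "sigma": float(np.mean([f.sigma for f in fits])),
        "latency_mod": float(np.mean(lat)) if lat else None,
        "n_tasks": len(fits),
    }
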