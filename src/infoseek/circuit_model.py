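"""Five-unit cortico-basal-ganglia rate circuit and virtual inactivations.

The circuit is a feed-forward affine rate model of the information-seeking
network: ACC receives the information signal ``I`` (1 on Info-CS trials),
drives icbDS, which inhibits Pal; a Visual unit responds to a contralateral
stimulus ``S``; the Gaze unit sums excitatory Visual input and inhibitory Pal
input plus trial-wise Gaussian noise::

    r_ACC    = w_ACC + I * w_I->ACC
    r_icbDS  = w_icbDS + r_ACC * w_ACC->icbDS
    r_Pal    = w_Pal + r_icbDS * w_icbDS->Pal
    r_Visual = w_Visual + S * w_S->Visual
    r_Gaze   = w_Gaze + r_Visual * w_Visual->Gaze + r_Pal * w_Pal->Gaze + eps

Muscimol inactivation is modeled by multiplying the inactivated area's rate
by a scaling factor (0.7 by default, i.e. a 30% rate reduction) before it
propagates.  Trial Gaze rates are turned into reaction times by rank-matching
against a reference RT pool: the trial with the Kth highest Gaze rate gets
the Kth fastest reference RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_session import ValidationError
from .inactivation import InactivationSession

__all__ = [
    "CircuitParams",
    "TrialInput",
    "Rates",
    "simulate_rates",
    "gaze_rates",
    "rates_to_rts",
    "default_rt_pool",
    "run_virtual_experiment",
]


@dataclass(frozen=True)
class CircuitParams:
    """Baselines, connection weights, noise, and inactivation scaling.

    All rates are in arbitrary firing-rate units chosen to approximate the
    typical pre-cue rates of information-related neurons in each area.
    """

    w_acc: float = 2.0
    w_icbds: float = 0.0
    w_pal: float = 50.0
    w_visual: float = 0.0
    w_gaze: float = 0.0
    w_i_to_acc: float = 20.0
    w_s_to_visual: float = 100.0
    w_acc_to_icbds: float = 1.0
    w_icbds_to_pal: float = -2.0
    w_visual_to_gaze: float = 1.0
    w_pal_to_gaze: float = -1.0
    noise_sd: float = 30.0
    inact_scale: float = 0.7

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 < self.inact_scale <= 1.0:
            raise ValidationError("inact_scale must be in (0, 1]")


@dataclass(frozen=True)
class TrialInput:
    """Binary trial inputs: I = Info CS shown; S = contralateral stimulus."""

    I: int
    S: int

    def __post_init__(self) -> None:
        if self.I not in (0, 1) or self.S not in (0, 1):
            raise ValidationError("trial inputs must be binary")


@dataclass(frozen=True)
class Rates:
    acc: float
    icbds: float
    pal: float
    visual: float
    gaze: float


def simulate_rates(params: CircuitParams, trial_input: TrialInput,
                   inactivated: str = "none",
                   seed: Optional[int] = None,
                   eps: Optional[float] = None) -> Rates:
    """Feed-forward evaluation of the circuit for one trial.

    ``inactivated`` in {"none", "icbDS", "Pal"} multiplies that area's rate
    by ``params.inact_scale`` before it propagates.  The Gaussian noise term
    on the Gaze unit is drawn from ``seed`` unless ``eps`` is given
    explicitly (``eps=0`` gives the deterministic rates).
    """
    if inactivated not in ("none", "icbDS", "Pal"):
        raise ValidationError(f"unknown inactivation target {inactivated!r}")
    r_acc = params.w_acc + trial_input.I * params.w_i_to_acc
    r_icbds = params.w_icbds + r_acc * params.w_acc_to_icbds
    if inactivated == "icbDS":
        r_icbds *= params.inact_scale
    r_pal = params.w_pal + r_icbds * params.w_icbds_to_pal
    if inactivated == "Pal":
        r_pal *= params.inact_scale
    r_visual = params.w_visual + trial_input.S * params.w_s_to_visual
    if eps is None:
        eps = float(np.random.default_rng(seed).normal(0.0, params.noise_sd))
    r_gaze = (params.w_gaze + r_visual * params.w_visual_to_gaze
              + r_pal * params.w_pal_to_gaze + eps)
    return Rates(acc=r_acc, icbds=r_icbds, pal=r_pal, visual=r_visual,
                 gaze=r_gaze)


def gaze_rates(params: CircuitParams, I: np.ndarray, S: np.ndarray,
               inactivated: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Vectorized Gaze-unit rates for arrays of trials.

    ``inactivated`` is a per-trial array of "none" / "icbDS" / "Pal".
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    inact = np.asarray(inactivated)
    r_acc = params.w_acc + I * params.w_i_to_acc
    r_icbds = params.w_icbds + r_acc * params.w_acc_to_icbds
    r_icbds = np.where(inact == "icbDS", r_icbds * params.inact_scale,
                       r_icbds)
    r_pal = params.w_pal + r_icbds * params.w_icbds_to_pal
    r_pal = np.where(inact == "Pal", r_pal * params.inact_scale, r_pal)
    r_visual = params.w_visual + S * params.w_s_to_visual
    eps = rng.normal(0.0, params.noise_sd, size=I.shape)
    return (params.w_gaze + r_visual * params.w_visual_to_gaze
            + r_pal * params.w_pal_to_gaze + eps)


def rates_to_rts(gaze_rate_values: Sequence, reference_rts: Sequence
                 ) -> np.ndarray:
    """Rank-match Gaze rates onto a reference RT pool.

    The trial with the Kth highest Gaze rate receives the Kth fastest
    reference RT; ties in rate are broken by stable input order.  The output
    is a permutation of ``reference_rts``.
    """
    rates = np.asarray(gaze_rate_values, dtype=float)
    rts = np.asarray(reference_rts, dtype=float)
    if rates.size != rts.size:
        raise ValidationError("rates and reference RTs must have equal length")
    order = np.argsort(-rates, kind="stable")
    out = np.empty_like(rts)
    out[order] = np.sort(rts)
    return out


def default_rt_pool(n: int, rng: np.random.Generator,
                    median_s: float = 0.25, sigma: float = 0.3) -> np.ndarray:
    """Log-normal reference RT pool (median 0.25 s), a configurable stand-in
    for control-session RTs."""
    return rng.lognormal(mean=np.log(median_s), sigma=sigma, size=n)


def run_virtual_experiment(params: CircuitParams, schedule: pd.DataFrame,
                           inactivated: str = "none",
                           seed: Optional[int] = None,
                           reference_rts: Optional[Sequence] = None,
                           session_id: str = "sim",
                           animal_id: str = "simA",
                           injection_side: str = "left") -> InactivationSession:
    """Simulate one inactivation session.

    ``schedule`` needs columns ``epoch`` (pre/post), ``cs_type``
    (info/noinfo), and ``cs_side`` (contra/ipsi).  Inactivation is applied
    only on post-epoch trials; Gaze rates are rank-mapped onto the reference
    RT pool (drawn from :func:`default_rt_pool` if not supplied) across the
    whole session.  The online RT is the offline RT plus small measurement
    noise, mirroring the dual RT records of the real acquisition system.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    I = (schedule["cs_type"].to_numpy() == "info").astype(float)
    S = (schedule["cs_side"].to_numpy() == "contra").astype(float)
    inact = np.where(schedule["epoch"].to_numpy() == "post", inactivated,
                     "none")
    rates = gaze_rates(params, I, S, inact, rng)
    pool = (np.asarray(reference_rts, dtype=float) if reference_rts is not None
            else default_rt_pool(n, rng))
    rt = rates_to_rts(rates, pool)
    rt_online = rt + rng.normal(0.0, 0.03, size=n)
    trials = schedule.copy()
    trials["rt"] = rt
    trials["rt_online"] = np.clip(rt_online, 1e-3, None)
    area = {"icbDS": "icbDS", "Pal": "Pal", "none": "control_saline"}[
        inactivated]
    return InactivationSession(session_id=session_id, animal_id=animal_id,
                               area=area, injection_side=injection_side,
                               trials=trials)
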