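"""Synthetic session generators with the statistical structure the analysis
stages assume.

The generators emulate the two task families:

* **Standard uncertainty task** -- five fractal CSs predicting reward with
  0/25/50/75/100% probability, displayed for 2.5 s; uncertainty-tuned neurons
  ramp up (or down) to the outcome with an inverted-U dependence on reward
  probability.
* **Information task** -- Info/Noinfo CSs at 0/50/100% reward probability
  (CS 1 s, cue 2 s, outcome at 3 s); "hypothesis 1" neurons anticipate the
  *moment of gaining information*, ramping to the informative cue on Info
  trials and to the outcome on Noinfo trials.

Spikes are drawn from an inhomogeneous Poisson process whose rate follows the
gaze-modulation equation ``rate = beta(c, t) * (1 + GazeMod * w_gain) +
GazeMod * w_offset`` (clipped at 0 spikes/s), given a simulated gaze trace.
Gaze is a two-state (on/off stimulus) Markov chain in position space: "on"
samples jitter around the CS center inside the 3-degree window, "off" samples
jitter around a far point; per-millisecond transition hazards may depend on
condition and trial time, which is how uncertainty-attracted gaze is modeled.

A single global seed expands into per-trial substreams by counter-based
splitting (``numpy`` ``SeedSequence`` spawn keys), so changing the trial
count never reshuffles earlier trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_session import Condition, NeuronSession, Trial, ValidationError
from .gaze_events import (NOINFO_CUE_ID, NOMINAL_CENTERS, NOREWARD_CUE_ID,
                          REWARD_CUE_ID)
from .gaze_model import gazemod

__all__ = [
    "NeuronSpec",
    "GazeBehaviorSpec",
    "uncertainty_conditions",
    "info_conditions",
    "uncertainty_neuron_spec",
    "info_neuron_spec",
    "uncertainty_attracted_gaze_spec",
    "gen_uncertainty_session",
    "gen_info_session",
    "gen_inactivation_dataset",
    "gen_lick_trace",
]

PROFILE_BIN_S = 0.05
STANDARD_T_OUTCOME = 2.5
INFO_T_CUE = 1.0
INFO_T_OUTCOME = 3.0
POST_OUTCOME_PAD_S = 0.2

Hazard = Union[float, dict, Callable]


@dataclass
class NeuronSpec:
    """Generative parameters of one synthetic neuron.

    ``base_profiles`` maps each condition to its gaze-off rate profile in
    spikes/s per 50 ms bin (the generative ``beta(c, t)``); ``w_gain`` /
    ``w_offset`` / ``mu`` / ``sigma`` are the gaze-modulation parameters of
    the rate equation, and ``sign_S`` the neuron's sign of uncertainty coding.
    Modulated rates are clipped at 0 spikes/s (Poisson rates must be
    non-negative); recovery tests should stay out of the clipped regime.
    """

    base_profiles: dict
    w_gain: float = 0.0
    w_offset: float = 0.0
    mu: float = 0.0
    sigma: float = 0.1
    sign_S: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.mu <= 1.0:
            raise ValidationError("mu must be in [-1, 1]")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValidationError("sigma must be in [0, 1]")
        if self.sign_S not in (-1, 1):
            raise ValidationError("sign_S must be -1 or +1")
        for c, prof in self.base_profiles.items():
            if np.any(np.asarray(prof) < 0):
                raise ValidationError(f"negative base profile for {c}")


@dataclass
class GazeBehaviorSpec:
    """Two-state Markov gaze behavior.

    ``p_shift_on`` is the per-ms hazard of shifting onto the stimulus while
    off it; ``p_shift_off`` the hazard of leaving while on it.  Each may be a
    float, a ``{condition: value}`` dict, or a callable ``f(condition, n_ms)
    -> per-ms array``, enabling condition- and epoch-dependent gaze
    attraction.  Defaults give bout lengths of a few hundred ms and roughly
    balanced on/off occupancy, as seen in free-viewing task behavior.
    """

    p_shift_on: Hazard = 0.002
    p_shift_off: Hazard = 0.0015
    fixation_jitter_sd: float = 0.5
    blink_rate: float = 0.2          # blinks per second
    blink_mean_ms: float = 80.0
    off_distance: float = 10.0       # deg, far-point distance from CS center


def _hazard_array(h: Hazard, condition: Condition, n_ms: int) -> np.ndarray:
    if callable(h):
        arr = np.asarray(h(condition, n_ms), dtype=float)
    elif isinstance(h, dict):
        arr = np.asarray(h[condition], dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_ms, float(arr))
    else:
        arr = np.full(n_ms, float(h))
    if arr.shape != (n_ms,):
        raise ValidationError("hazard array has wrong length")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("hazards must lie in [0, 1]")
    return arr


def _sample_state_trace(rng: np.random.Generator, h_on: np.ndarray,
                        h_off: np.ndarray) -> np.ndarray:
    """Alternating-bout sampling of the on/off chain with time-varying
    hazards (inverse-CDF on the cumulative hazard)."""
    n = h_on.size
    state = np.empty(n, dtype=np.int8)
    p0 = h_on[0] / max(h_on[0] + h_off[0], 1e-12)
    s = 1 if rng.random() < p0 else 0
    t = 0
    logs_on = np.cumsum(np.log1p(-np.clip(h_on, 0.0, 1.0 - 1e-12)))
    logs_off = np.cumsum(np.log1p(-np.clip(h_off, 0.0, 1.0 - 1e-12)))
    while t < n:
        logs = logs_off if s == 1 else logs_on
        base = logs[t - 1] if t > 0 else 0.0
        target = base + math.log(max(rng.random(), 1e-300))
        # first index >= t with cumulative log-survival <= target
        nxt = np.searchsorted(-logs[t:], -target, side="left") + t
        nxt = min(nxt + 1, n)  # transition happens after surviving nxt-t steps
        state[t:nxt] = s
        s = 1 - s
        t = nxt
    return state


def _simulate_gaze(rng: np.random.Generator, condition: Condition,
                   gaze_spec: GazeBehaviorSpec, n_ms: int) -> tuple:
    """Returns (gaze array (n_ms, 3), latent on-flags)."""
    center = np.array(NOMINAL_CENTERS[condition.cs_location])
    h_on = _hazard_array(gaze_spec.p_shift_on, condition, n_ms)
    h_off = _hazard_array(gaze_spec.p_shift_off, condition, n_ms)
    state = _sample_state_trace(rng, h_on, h_off)
    far = center + np.array([gaze_spec.off_distance, 0.0])
    jitter = rng.normal(0.0, gaze_spec.fixation_jitter_sd, size=(n_ms, 2))
    # keep on-state samples inside the 3 deg window despite jitter
    jitter_on = np.clip(jitter, -2.0, 2.0)
    pos = np.where(state[:, None] == 1, center + jitter_on, far + jitter)
    blink = np.zeros(n_ms)
    n_blinks = rng.poisson(gaze_spec.blink_rate * n_ms / 1000.0)
    for _ in range(n_blinks):
        b0 = rng.integers(0, n_ms)
        dur = 1 + rng.geometric(1.0 / gaze_spec.blink_mean_ms)
        blink[b0:b0 + dur] = 1.0
    gaze = np.column_stack([pos, blink])
    return gaze, state.astype(float)


def _profile_to_ms(profile: np.ndarray, n_ms: int) -> np.ndarray:
    per_bin = int(round(PROFILE_BIN_S * 1000))
    r = np.repeat(np.asarray(profile, dtype=float), per_bin)
    if r.size < n_ms:
        r = np.pad(r, (0, n_ms - r.size), mode="edge")
    return r[:n_ms]


def _spikes_from_rate(rng: np.random.Generator,
                      rate_per_s: np.ndarray) -> np.ndarray:
    counts = rng.poisson(np.clip(rate_per_s, 0.0, None) * 0.001)
    ms_idx = np.repeat(np.arange(counts.size), counts)
    if ms_idx.size == 0:
        return np.empty(0)
    return np.sort((ms_idx + rng.random(ms_idx.size)) / 1000.0)


def _gen_trial(spec: NeuronSpec, gaze_spec: GazeBehaviorSpec,
               condition: Condition, duration: float, t_outcome: float,
               t_cue_on: Optional[float],
               rng: np.random.Generator) -> Trial:
    if condition not in spec.base_profiles:
        raise ValidationError(f"missing base profile for condition {condition}")
    n_ms = int(math.floor(1000.0 * duration))
    gaze, flags = _simulate_gaze(rng, condition, gaze_spec, n_ms)
    gm = gazemod(flags, spec.mu, spec.sigma)
    beta = _profile_to_ms(spec.base_profiles[condition], n_ms)
    rate = beta * (1.0 + gm * spec.w_gain) + gm * spec.w_offset
    spikes = _spikes_from_rate(rng, rate)
    return Trial(condition=condition, duration=duration, t_outcome=t_outcome,
                 spikes=spikes, gaze=gaze, t_cue_on=t_cue_on)


def _trial_rng(seed: int, cond_index: int, trial_index: int
               ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(cond_index, trial_index)))


# ---------------------------------------------------------------------------
# Condition sets and neuron-spec factories
# ---------------------------------------------------------------------------

def uncertainty_conditions(cs_location: str = "center") -> list:
    """The five reward-probability conditions of the standard task."""
    return [Condition(task_id="standard_uncertainty", cs_kind="standard",
                      reward_prob=p, cs_location=cs_location)
            for p in (0.0, 0.25, 0.5, 0.75, 1.0)]


def info_conditions(cs_location: str = "center") -> list:
    """The seven CS-by-cue conditions of the information task."""
    c = []
    for p, cue in [(1.0, REWARD_CUE_ID), (0.5, REWARD_CUE_ID),
                   (0.5, NOREWARD_CUE_ID), (0.0, NOREWARD_CUE_ID)]:
        c.append(Condition(task_id="info", cs_kind="info", reward_prob=p,
                           cue_id=cue, cs_location=cs_location))
    for p in (1.0, 0.5, 0.0):
        c.append(Condition(task_id="info", cs_kind="noinfo", reward_prob=p,
                           cue_id=NOINFO_CUE_ID, cs_location=cs_location))
    return c


def _ramp(base: float, peak: float, n_bins: int, start: int, stop: int
          ) -> np.ndarray:
    prof = np.full(n_bins, base)
    prof[start:stop] = np.linspace(base, peak, stop - start)
    prof[stop:] = prof[stop - 1] if stop > start else base
    return prof


def uncertainty_neuron_spec(peak_rates: Optional[dict] = None,
                            base_rate: float = 2.0,
                            w_gain: float = 0.0, w_offset: float = 0.0,
                            mu: float = 0.0, sigma: float = 0.1,
                            sign_S: int = 1,
                            cs_location: str = "center") -> NeuronSpec:
    """Inverted-U uncertainty-tuned neuron for the standard task.

    The default peak rates (at outcome time) follow the inverted-U:
    strongest at 50%, intermediate at 25/75%, weak at 0/100%.  Profiles ramp
    linearly from ``base_rate`` at CS onset to the peak at the outcome.
    """
    if peak_rates is None:
        peak_rates = {0.0: 2.0, 0.25: 10.0, 0.5: 16.0, 0.75: 10.0, 1.0: 2.0}
    duration = STANDARD_T_OUTCOME + POST_OUTCOME_PAD_S
    n_bins = int(round(duration / PROFILE_BIN_S))
    stop = int(round(STANDARD_T_OUTCOME / PROFILE_BIN_S))
    profiles = {}
    for cond in uncertainty_conditions(cs_location):
        peak = peak_rates[cond.reward_prob]
        profiles[cond] = _ramp(base_rate, peak, n_bins, 0, stop)
    return NeuronSpec(base_profiles=profiles, w_gain=w_gain,
                      w_offset=w_offset, mu=mu, sigma=sigma, sign_S=sign_S)


def info_neuron_spec(hypothesis: int = 1, base_rate: float = 2.0,
                     peak_rate: float = 20.0,
                     w_gain: float = 0.0, w_offset: float = 0.0,
                     mu: float = 0.0, sigma: float = 0.1,
                     sign_S: int = 1,
                     cs_location: str = "center") -> NeuronSpec:
    """Information-task neuron profiles.

    ``hypothesis=1`` (information anticipation): activity ramps to the
    informative cue on uncertain Info trials and to the outcome on uncertain
    Noinfo trials.  ``hypothesis=2`` (uncertain-outcome anticipation):
    identical Info/Noinfo profiles during the CS period; after the cue, Info
    activity collapses (outcome known) while Noinfo activity keeps ramping to
    the outcome.  ``hypothesis=0`` gives flat, condition-independent profiles
    (an exchangeable null).
    """
    duration = INFO_T_OUTCOME + POST_OUTCOME_PAD_S
    n_bins = int(round(duration / PROFILE_BIN_S))
    cue_bin = int(round(INFO_T_CUE / PROFILE_BIN_S))
    out_bin = int(round(INFO_T_OUTCOME / PROFILE_BIN_S))
    profiles = {}
    for cond in info_conditions(cs_location):
        flat = np.full(n_bins, base_rate)
        if hypothesis == 0 or not cond.uncertain:
            profiles[cond] = flat
            continue
        if hypothesis == 1:
            if cond.cs_kind == "info":
                prof = flat.copy()
                prof[:cue_bin] = np.linspace(base_rate, peak_rate, cue_bin)
                profiles[cond] = prof    # drops to base once informed
            else:
                prof = flat.copy()
                prof[cue_bin:out_bin] = np.linspace(base_rate, peak_rate,
                                                    out_bin - cue_bin)
                prof[out_bin:] = base_rate
                profiles[cond] = prof
        elif hypothesis == 2:
            prof = flat.copy()
            prof[:cue_bin] = np.linspace(base_rate, peak_rate / 2.0, cue_bin)
            if cond.cs_kind == "noinfo":
                prof[cue_bin:out_bin] = np.linspace(peak_rate / 2.0,
                                                    peak_rate,
                                                    out_bin - cue_bin)
                prof[out_bin:] = base_rate
            else:
                prof[cue_bin:] = base_rate
            profiles[cond] = prof
        else:
            raise ValidationError("hypothesis must be 0, 1, or 2")
    return NeuronSpec(base_profiles=profiles, w_gain=w_gain,
                      w_offset=w_offset, mu=mu, sigma=sigma, sign_S=sign_S)


def uncertainty_attracted_gaze_spec(base_on: float = 0.002,
                                    base_off: float = 0.0015,
                                    attraction: float = 8.0,
                                    avoidance: float = 6.0
                                    ) -> GazeBehaviorSpec:
    """Gaze behavior attracted to uncertainty-resolving stimuli.

    Emulates the observed free-viewing structure of the tasks: while the
    outcome is uncertain, the hazard of shifting onto the stimulus ramps up
    (exponentially, by a factor of ``attraction``) over the epoch that ends
    with the next informative event -- the CS period on Info trials, the cue
    period on Noinfo trials, the whole CS period in the standard task --
    so the gaze-on probability climbs toward ~0.9 just before information
    arrives.  Stimuli known to predict no reward are avoided: the hazard of
    leaving ramps up by ``avoidance`` (0% CSs, and the stimulus after a
    no-reward informative cue).  Certain-reward stimuli keep the baseline,
    roughly value-based occupancy.
    """

    def _ramp(n_ms: int, a: int, b: int, factor: float) -> np.ndarray:
        r = np.ones(n_ms)
        a, b = max(a, 0), min(b, n_ms)
        if b > a:
            r[a:b] = factor ** np.linspace(0.0, 1.0, b - a)
            r[b:] = factor
        return r

    def _epochs(cond: Condition, n_ms: int):
        """(attraction multiplier, avoidance multiplier) per ms."""
        att = np.ones(n_ms)
        avo = np.ones(n_ms)
        if cond.task_id == "standard_uncertainty":
            t_out = int(STANDARD_T_OUTCOME * 1000)
            if cond.uncertain:
                att = _ramp(n_ms, 0, t_out, attraction)
            elif cond.reward_prob == 0.0:
                avo = _ramp(n_ms, 0, t_out, avoidance)
            return att, avo
        t_cue = int(INFO_T_CUE * 1000)
        t_out = int(INFO_T_OUTCOME * 1000)
        if cond.reward_prob == 0.0:
            avo = _ramp(n_ms, 0, t_out, avoidance)
        elif cond.uncertain:
            if cond.cs_kind == "info":
                # anticipates the informative cue; afterwards the cue
                # resolves the outcome (avoid the no-reward cue)
                att = _ramp(n_ms, 0, t_cue, attraction)
                att[t_cue:] = 1.0
                if cond.cue_id == NOREWARD_CUE_ID:
                    avo = _ramp(n_ms, t_cue, t_out, avoidance)
            else:
                att = _ramp(n_ms, t_cue, t_out, attraction)
                att[min(t_out, n_ms):] = 1.0
        return att, avo

    def h_on(cond: Condition, n_ms: int) -> np.ndarray:
        att, avo = _epochs(cond, n_ms)
        return np.clip(base_on * att / avo, 0.0, 1.0)

    def h_off(cond: Condition, n_ms: int) -> np.ndarray:
        att, avo = _epochs(cond, n_ms)
        return np.clip(base_off * avo, 0.0, 1.0)

    return GazeBehaviorSpec(p_shift_on=h_on, p_shift_off=h_off)


# ---------------------------------------------------------------------------
# Session generators
# ---------------------------------------------------------------------------

def gen_uncertainty_session(spec: NeuronSpec, gaze_spec: GazeBehaviorSpec,
                            n_per_cond: int, seed: int,
                            neuron_id: str = "sim-std", area: str = "ACC",
                            animal_id: str = "simA",
                            cs_location: str = "center") -> NeuronSession:
    """Standard-uncertainty-task session: 5 probability conditions, 2.5 s CS
    epoch, spikes from an inhomogeneous Poisson process driven by the
    gaze-modulated rate; deterministic given ``seed``."""
    if n_per_cond < 1:
        raise ValidationError("n_per_cond must be >= 1")
    conds = uncertainty_conditions(cs_location)
    duration = STANDARD_T_OUTCOME + POST_OUTCOME_PAD_S
    trials = []
    for k in range(n_per_cond):
        for ci, cond in enumerate(conds):
            rng = _trial_rng(seed, ci, k)
            trials.append(_gen_trial(spec, gaze_spec, cond, duration,
                                     STANDARD_T_OUTCOME, None, rng))
    return NeuronSession(neuron_id=neuron_id, area=area, animal_id=animal_id,
                         trials=trials)


def gen_info_session(spec: NeuronSpec, gaze_spec: GazeBehaviorSpec,
                     n_per_cond: int, seed: int,
                     neuron_id: str = "sim-info", area: str = "icbDS",
                     animal_id: str = "simA",
                     cs_location: str = "center") -> NeuronSession:
    """Information-task session: Info/Noinfo at 0/50/100% reward, CS 1 s,
    cue 2 s, outcome at 3 s."""
    if n_per_cond < 1:
        raise ValidationError("n_per_cond must be >= 1")
    conds = info_conditions(cs_location)
    missing = [c for c in conds if c not in spec.base_profiles]
    if missing:
        raise ValidationError(f"missing condition profiles: {missing}")
    duration = INFO_T_OUTCOME + POST_OUTCOME_PAD_S
    trials = []
    for k in range(n_per_cond):
        for ci, cond in enumerate(conds):
            rng = _trial_rng(seed, ci, k)
            trials.append(_gen_trial(spec, gaze_spec, cond, duration,
                                     INFO_T_OUTCOME, INFO_T_CUE, rng))
    return NeuronSession(neuron_id=neuron_id, area=area, animal_id=animal_id,
                         trials=trials)


def gen_inactivation_dataset(circuit, n_sessions: int,
                             n_trials_pre: int = 100,
                             n_trials_post: int = 300,
                             inactivated_area: str = "none",
                             scale: float = 0.7, seed: int = 0,
                             animals: Sequence[str] = ("simA", "simB"),
                             reference_pool=None) -> list:
    """Simulated muscimol-inactivation sessions.

    Each session runs the rate-circuit model for ``n_trials_pre`` pre- and
    ``n_trials_post`` post-injection trials (Info/Noinfo and contra/ipsi
    assigned at random), with the inactivated area's rate scaled by ``scale``
    on post trials, and rank-maps Gaze rates onto a reference RT pool.
    """
    from dataclasses import replace as _replace

    from .circuit_model import run_virtual_experiment

    if not 0.0 < scale <= 1.0:
        raise ValidationError("scale must be in (0, 1]")
    params = _replace(circuit, inact_scale=scale)
    sessions = []
    for s in range(n_sessions):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(s,)))
        n = n_trials_pre + n_trials_post
        schedule = pd.DataFrame({
            "epoch": ["pre"] * n_trials_pre + ["post"] * n_trials_post,
            "cs_type": rng.choice(["info", "noinfo"], size=n),
            "cs_side": rng.choice(["contra", "ipsi"], size=n),
        })
        sessions.append(run_virtual_experiment(
            params, schedule, inactivated=inactivated_area,
            seed=int(rng.integers(0, 2 ** 31)),
            reference_rts=reference_pool,
            session_id=f"{inactivated_area}-{s}",
            animal_id=animals[s % len(animals)]))
    return sessions


def gen_lick_trace(trial_duration: float, lick_epochs: Sequence,
                   noise_sd: float = 1.0, seed: int = 0,
                   amplitude: Optional[float] = None,
                   lick_freq_hz: float = 4.0) -> np.ndarray:
    """Synthetic strain-gauge trace: Gaussian baseline noise plus
    high-amplitude oscillatory bursts inside the lick epochs."""
    rng = np.random.default_rng(seed)
    n_ms = int(math.floor(1000.0 * trial_duration))
    if amplitude is None:
        amplitude = 10.0 * noise_sd
    t = np.arange(n_ms) / 1000.0
    trace = rng.normal(0.0, noise_sd, size=n_ms)
    for (a, b) in lick_epochs:
        if not (0.0 <= a < b <= trial_duration):
            raise ValidationError("lick epoch outside the trial")
        sel = (t >= a) & (t < b)
        trace[sel] += amplitude * np.sin(2.0 * np.pi * lick_freq_hz * t[sel])
    return trace
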