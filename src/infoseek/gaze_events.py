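"""Gaze-window calibration, gaze-shift detection with matched controls,
gaze-state activity comparisons, lick detection, and behavioral indexes.

Gaze is "on the stimulus" when the eye is within a 3-degree-radius circular
window around the CS.  Because eye-tracker calibration drifts between
sessions, the window center is re-estimated per session and CS location as
the peak of a smoothed 2-D histogram of eye positions near the nominal
stimulus center.

Gaze *shifts* are criterion-based transitions between stable on/off states
(>= 150 ms in the initial state, >= 100 ms in the new state, a genuine
excursion of >= 5 degrees, no blink in the preceding 100 ms).  Each shift is
paired with matched *control* non-shift events -- same CS, same cue type,
same time point in the trial, same prior gaze state, but where the gaze
stayed put -- selected so that the control-minus-shift gaze distances 50 ms
before the event are small and balanced around zero.  Shift-aligned activity
is always reported relative to the mean over an event's own controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .core_session import (AnalysisWindow, NeuronSession, Trial,
                           ValidationError, window_slice)
from .signal_analysis import (AnticipationIndexes, NormalizedActivity,
                              anticipation_indexes_from_values)

__all__ = [
    "NOMINAL_CENTERS",
    "REWARD_CUE_ID",
    "NOREWARD_CUE_ID",
    "NOINFO_CUE_ID",
    "GazeState",
    "gaze_on_flags",
    "gaze_distance",
    "calibrate_gaze_window",
    "gaze_state_activity_compare",
    "GazeShiftEvent",
    "detect_gaze_shifts",
    "match_controls",
    "detect_and_match_shifts",
    "knowledge_prob",
    "condition_group",
    "shift_aligned_activity",
    "population_shift_aligned",
    "lick_threshold",
    "detect_licks",
    "behavioral_anticipation_indexes",
    "gaze_probability_timecourse",
]

#: Nominal stimulus centers in degrees by screen location.
NOMINAL_CENTERS = {"center": (0.0, 0.0), "left": (-10.0, 0.0),
                   "right": (10.0, 0.0)}

#: Cue-id conventions used by the synthetic generators: informative cues
#: reveal the outcome (reward / no reward); noninformative cues do not.
REWARD_CUE_ID = 1
NOREWARD_CUE_ID = 2
NOINFO_CUE_ID = 3

GAZE_RADIUS_DEG = 3.0


@dataclass
class GazeState:
    """Per-millisecond gaze-on-stimulus flags for one trial."""

    flags: np.ndarray            # 0/1 per ms (blinks carry the last state)
    center: tuple                # (x, y) window center in degrees
    radius: float = GAZE_RADIUS_DEG


def _carry_blinks(values: np.ndarray, blink: np.ndarray) -> np.ndarray:
    """Replace blink samples with the last non-blink value (state-preserving)."""
    out = values.copy()
    bad = blink.astype(bool)
    if not bad.any():
        return out
    idx = np.arange(out.size)
    idx[bad] = 0
    idx = np.maximum.accumulate(idx)
    out = out[idx]
    # leading blinks: carry the first valid value backwards
    first = np.argmax(~bad) if (~bad).any() else 0
    out[:first] = values[first]
    return out


def gaze_on_flags(trial: Trial, center: tuple,
                  radius: float = GAZE_RADIUS_DEG) -> np.ndarray:
    """Binary per-ms gaze-on-stimulus flags; blinks preserve the last state."""
    dx = trial.gaze[:, 0] - center[0]
    dy = trial.gaze[:, 1] - center[1]
    on = (np.hypot(dx, dy) < radius).astype(float)
    return _carry_blinks(on, trial.gaze[:, 2])


def gaze_distance(trial: Trial, center: tuple) -> np.ndarray:
    """Per-ms Euclidean distance (deg) to the window center; NaN at blinks."""
    d = np.hypot(trial.gaze[:, 0] - center[0], trial.gaze[:, 1] - center[1])
    d = d.copy()
    d[trial.gaze[:, 2].astype(bool)] = np.nan
    return d


def calibrate_gaze_window(session: NeuronSession, cs_location: str,
                          bin_deg: float = 0.25, blur_deg: float = 0.5,
                          search_radius: float = 8.0) -> tuple:
    """Re-center the gaze window on the observed peak of eye positions.

    Uses samples from all reward-associated CS trials at ``cs_location``,
    from 0.2 s after CS onset to 0.1 s after CS offset, within
    ``search_radius`` degrees of the nominal center; the center is the argmax
    of a 2-D histogram (0.25 degree bins) blurred with a Gaussian of SD 0.5
    degrees.  Falls back to the nominal center with a warning if no samples
    qualify.
    """
    nominal = np.array(NOMINAL_CENTERS[cs_location])
    samples = []
    for tr in session.trials:
        c = tr.condition
        if c.cs_location != cs_location or c.reward_prob == 0.0:
            continue
        cs_off = tr.t_cue_on if tr.t_cue_on is not None else tr.t_outcome
        w = window_slice(tr, AnalysisWindow(0.2, cs_off + 0.1, "cs_on"))
        g = w.gaze
        g = g[g[:, 2] == 0]  # drop blinks
        d = np.hypot(g[:, 0] - nominal[0], g[:, 1] - nominal[1])
        samples.append(g[d < search_radius, :2])
    pts = np.concatenate(samples) if samples else np.empty((0, 2))
    if pts.shape[0] == 0:
        warnings.warn(f"no gaze samples near the nominal {cs_location} CS "
                      "center; using the nominal center")
        return tuple(nominal)
    edges_x = np.arange(nominal[0] - search_radius,
                        nominal[0] + search_radius + bin_deg, bin_deg)
    edges_y = np.arange(nominal[1] - search_radius,
                        nominal[1] + search_radius + bin_deg, bin_deg)
    hist, ex, ey = np.histogram2d(pts[:, 0], pts[:, 1],
                                  bins=[edges_x, edges_y])
    hist = ndimage.gaussian_filter(hist, sigma=blur_deg / bin_deg)
    i, j = np.unravel_index(np.argmax(hist), hist.shape)
    return (float((ex[i] + ex[i + 1]) / 2.0), float((ey[j] + ey[j + 1]) / 2.0))


def _pre_information_window(trial: Trial) -> AnalysisWindow:
    """0.5 s window immediately before the trial's next informative event."""
    c = trial.condition
    if c.task_id == "standard_uncertainty" or c.cs_kind == "noinfo":
        return AnalysisWindow(trial.t_outcome - 0.5, trial.t_outcome, "cs_on")
    return AnalysisWindow(trial.t_cue_on - 0.5, trial.t_cue_on, "cs_on")


def gaze_state_activity_compare(session: NeuronSession,
                                activity: NormalizedActivity,
                                centers: Optional[dict] = None,
                                radius: float = GAZE_RADIUS_DEG
                                ) -> Optional[dict]:
    """Mean normalized activity split by gaze state, matched millisecond by
    millisecond.

    For every condition and the 0.5 s window immediately before receipt of
    information (pre-outcome in standard tasks; pre-cue on Info trials and
    pre-outcome on Noinfo trials in information tasks), the per-state mean is
    computed at each millisecond where both gaze states are represented, then
    averaged over valid milliseconds.  Returns ``{condition: (mean_on,
    mean_off)}``, or ``None`` (neuron excluded) if any condition has no valid
    millisecond.
    """
    out = {}
    for cond in session.conditions():
        idx = [i for i, t in enumerate(session.trials) if t.condition == cond]
        trials = [session.trials[i] for i in idx]
        w = _pre_information_window(trials[0])
        ms0 = int(round(w.t_start * 1000))
        ms1 = int(round(w.t_end * 1000))
        center = (centers or {}).get(cond.cs_location,
                                     NOMINAL_CENTERS[cond.cs_location])
        flags = np.stack([gaze_on_flags(t, center, radius)[ms0:ms1]
                          for t in trials]).astype(bool)
        act = activity.traces[idx][:, ms0:ms1]
        n_on = flags.sum(0)
        valid = (n_on > 0) & (n_on < flags.shape[0])
        if not valid.any():
            return None
        on_mean = np.where(flags, act, np.nan)
        off_mean = np.where(~flags, act, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mo = np.nanmean(on_mean[:, valid], axis=0).mean()
            mf = np.nanmean(off_mean[:, valid], axis=0).mean()
        out[cond] = (float(mo), float(mf))
    return out


# ---------------------------------------------------------------------------
# Gaze shifts and matched controls
# ---------------------------------------------------------------------------

@dataclass
class GazeShiftEvent:
    """One gaze shift onto or off the stimulus, plus matched non-shift
    controls."""

    trial_index: int
    time: float                  # s (onto-shifts already corrected by -40 ms)
    direction: str               # "onto" | "off"
    detect_ms: int               # raw detection millisecond
    controls: list = field(default_factory=list)   # [(trial_index, time_s)]
    control_diffs: list = field(default_factory=list)  # deg, at -50 ms


def _run_lengths(flags: np.ndarray) -> tuple:
    """(back[t], fwd[t]): length of the constant-state run ending at / starting
    at t."""
    n = flags.size
    back = np.empty(n, dtype=int)
    fwd = np.empty(n, dtype=int)
    run = 0
    for t in range(n):
        run = run + 1 if t > 0 and flags[t] == flags[t - 1] else 1
        back[t] = run
    run = 0
    for t in range(n - 1, -1, -1):
        run = run + 1 if t < n - 1 and flags[t] == flags[t + 1] else 1
        fwd[t] = run
    return back, fwd


def detect_gaze_shifts(trial: Trial, state: GazeState,
                       trial_index: int = 0,
                       min_pre_ms: int = 150, min_post_ms: int = 100,
                       excursion_deg: float = 5.0,
                       blink_guard_ms: int = 100,
                       onto_correction_ms: int = 40) -> list:
    """Detect gaze shifts onto / off the stimulus in one trial.

    An *off*-shift at millisecond ``t`` requires a stable on-state for >= 150
    ms before ``t``, a stable off-state for >= 100 ms from ``t``, gaze at
    least 5 degrees from the window center 100 ms after ``t``, and no blink
    in the 100 ms before ``t``.  *Onto*-shifts use the mirrored criteria
    (gaze >= 5 degrees away 100 ms *before* the shift) and their reported
    time is ``t - 40 ms``, approximating when the eye movement began rather
    than when the eye entered the window.  Returned events carry no controls.
    """
    flags = state.flags.astype(int)
    n = flags.size
    dist_raw = np.hypot(trial.gaze[:, 0] - state.center[0],
                        trial.gaze[:, 1] - state.center[1])
    blink = trial.gaze[:, 2].astype(bool)
    back, fwd = _run_lengths(flags)
    events = []
    # transition points: flags[t] != flags[t-1]
    trans = np.flatnonzero(flags[1:] != flags[:-1]) + 1
    for t in trans:
        if back[t - 1] < min_pre_ms or fwd[t] < min_post_ms:
            continue
        if blink[max(0, t - blink_guard_ms):t].any():
            continue
        if flags[t] == 0:                      # off-shift
            if t + min_post_ms >= n:
                continue
            if dist_raw[t + min_post_ms] < excursion_deg:
                continue
            events.append(GazeShiftEvent(trial_index=trial_index,
                                         time=t / 1000.0, direction="off",
                                         detect_ms=t))
        else:                                  # onto-shift
            if t - min_post_ms < 0:
                continue
            if dist_raw[t - min_post_ms] < excursion_deg:
                continue
            t_rep = t - onto_correction_ms
            if t_rep < 0:
                continue
            events.append(GazeShiftEvent(trial_index=trial_index,
                                         time=t_rep / 1000.0,
                                         direction="onto", detect_ms=t))
    return events


def _distance_at(dist: np.ndarray, ms: int, max_gap_ms: int = 20
                 ) -> Optional[float]:
    """Distance at a sample, linearly interpolated across a blink gap of at
    most ``max_gap_ms``; None if unavailable."""
    if ms < 0 or ms >= dist.size:
        return None
    if not math.isnan(dist[ms]):
        return float(dist[ms])
    lo = ms
    while lo >= 0 and math.isnan(dist[lo]):
        lo -= 1
    hi = ms
    while hi < dist.size and math.isnan(dist[hi]):
        hi += 1
    if lo < 0 or hi >= dist.size:
        return None
    if hi - lo > max_gap_ms:
        return None
    f = (ms - lo) / (hi - lo)
    return float(dist[lo] * (1 - f) + dist[hi] * f)


def select_balanced_controls(diffs: Sequence[float]) -> list:
    """Greedy sign-balancing selection of control events.

    Pick the candidate with the smallest absolute distance difference first;
    then repeatedly pick the smallest-magnitude candidate whose difference
    sign opposes the running mean of the selected differences; stop when no
    candidate qualifies.  Returns the selected indexes in selection order.
    """
    remaining = list(range(len(diffs)))
    if not remaining:
        return []
    order = []
    first = min(remaining, key=lambda i: abs(diffs[i]))
    order.append(first)
    remaining.remove(first)
    while remaining:
        mean = sum(diffs[i] for i in order) / len(order)
        if mean > 0:
            cands = [i for i in remaining if diffs[i] < 0]
        elif mean < 0:
            cands = [i for i in remaining if diffs[i] > 0]
        else:
            cands = remaining
        if not cands:
            break
        pick = min(cands, key=lambda i: abs(diffs[i]))
        order.append(pick)
        remaining.remove(pick)
    return order


def match_controls(shift: GazeShiftEvent, session: NeuronSession,
                   flags_by_trial: Sequence[np.ndarray],
                   dist_by_trial: Sequence[np.ndarray],
                   min_pre_ms: int = 150, min_post_ms: int = 100
                   ) -> GazeShiftEvent:
    """Attach matched non-shift control events to a gaze shift.

    Control candidates are time points from other trials of the same neuron
    that (1)-(3) share the CS and cue type, (4) sit at the same time point in
    the trial, (5) spent the previous 150 ms in the shift's initial gaze
    state, and (6) stayed in that state for at least the next 100 ms.  From
    the candidates, a subset balancing the gaze-to-stimulus distance
    difference 50 ms before the event is selected
    (:func:`select_balanced_controls`).  An event that ends up with zero
    controls is returned with an empty list (to be dropped by the caller).
    """
    t_ms = int(round(shift.time * 1000.0))
    initial_state = 1 if shift.direction == "off" else 0
    shift_cond = session.trials[shift.trial_index].condition
    d_shift = _distance_at(dist_by_trial[shift.trial_index], t_ms - 50)
    if d_shift is None:
        shift.controls = []
        shift.control_diffs = []
        return shift
    cand, diffs = [], []
    for j, tr in enumerate(session.trials):
        if j == shift.trial_index:
            continue
        c = tr.condition
        if (c.reward_prob, c.cs_kind, c.cue_id, c.cs_location) != \
           (shift_cond.reward_prob, shift_cond.cs_kind, shift_cond.cue_id,
                shift_cond.cs_location):
            continue
        f = flags_by_trial[j]
        if t_ms - min_pre_ms < 0 or t_ms + min_post_ms > f.size:
            continue
        seg = f[t_ms - min_pre_ms:t_ms + min_post_ms]
        if not np.all(seg == initial_state):
            continue
        d = _distance_at(dist_by_trial[j], t_ms - 50)
        if d is None:
            continue
        cand.append((j, t_ms / 1000.0))
        diffs.append(d - d_shift)
    sel = select_balanced_controls(diffs)
    shift.controls = [cand[i] for i in sel]
    shift.control_diffs = [diffs[i] for i in sel]
    return shift


def detect_and_match_shifts(session: NeuronSession,
                            centers: Optional[dict] = None,
                            radius: float = GAZE_RADIUS_DEG) -> list:
    """Detect all gaze shifts in a session and attach matched controls.

    Events with no qualifying control are dropped.
    """
    flags_by_trial, dist_by_trial = [], []
    for tr in session.trials:
        center = (centers or {}).get(tr.condition.cs_location,
                                     NOMINAL_CENTERS[tr.condition.cs_location])
        flags_by_trial.append(gaze_on_flags(tr, center, radius).astype(int))
        dist_by_trial.append(gaze_distance(tr, center))
    events = []
    for i, tr in enumerate(session.trials):
        center = (centers or {}).get(tr.condition.cs_location,
                                     NOMINAL_CENTERS[tr.condition.cs_location])
        state = GazeState(flags=flags_by_trial[i], center=center,
                          radius=radius)
        for ev in detect_gaze_shifts(tr, state, trial_index=i):
            ev = match_controls(ev, session, flags_by_trial, dist_by_trial)
            if ev.controls:
                events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Knowledge state and shift-aligned activity
# ---------------------------------------------------------------------------

def knowledge_prob(trial: Trial, t: float) -> float:
    """The animal's current reward probability estimate at trial time ``t``.

    An informative cue updates the probability to 0 or 1 from cue onset; a
    noninformative cue leaves it unchanged; the outcome resolves everything.
    """
    c = trial.condition
    p = c.reward_prob
    if trial.t_cue_on is not None and t >= trial.t_cue_on:
        if c.cue_id == REWARD_CUE_ID:
            return 1.0
        if c.cue_id == NOREWARD_CUE_ID:
            return 0.0
    return p


def condition_group(trial: Trial, t: float) -> str:
    """Classify the knowledge state at time ``t``: ``certain-no-reward``,
    ``uncertain``, or ``certain-reward``."""
    p = knowledge_prob(trial, t)
    if p == 0.0:
        return "certain-no-reward"
    if p == 1.0:
        return "certain-reward"
    return "uncertain"


DEFAULT_SHIFT_WINDOWS = ((-0.4, -0.1), (-0.1, 0.1), (0.1, 0.4))
CONDITION_GROUPS = ("certain-no-reward", "uncertain", "certain-reward")


def _aligned_trace(traces: np.ndarray, trial_index: int, t_event: float,
                   pre_s: float, post_s: float) -> np.ndarray:
    n_ms = traces.shape[1]
    ms = int(round(t_event * 1000.0))
    lo = ms - int(round(pre_s * 1000))
    hi = ms + int(round(post_s * 1000))
    out = np.full(hi - lo, np.nan)
    a, b = max(lo, 0), min(hi, n_ms)
    if a < b:
        out[a - lo:b - lo] = traces[trial_index, a:b]
    return out


def shift_aligned_activity(events: Sequence[GazeShiftEvent],
                           session: NeuronSession,
                           activity: NormalizedActivity,
                           windows: Sequence = DEFAULT_SHIFT_WINDOWS,
                           pre_s: float = 0.4, post_s: float = 0.4
                           ) -> Optional[dict]:
    """Control-subtracted, shift-aligned normalized activity for one neuron.

    Each event contributes its aligned activity minus the mean aligned
    activity over its own control events; events are averaged per
    ``(direction, condition group)`` cell.  Neurons lacking any cell of the
    2 x 3 grid are excluded (returns ``None``).  The result maps each cell to
    its mean trace (``times``, ``trace``) and the mean in the three analysis
    windows before/during/after the shift.
    """
    cells = {(d, g): [] for d in ("onto", "off") for g in CONDITION_GROUPS}
    for ev in events:
        if not ev.controls:
            continue
        tr = session.trials[ev.trial_index]
        group = condition_group(tr, ev.time)
        evt = _aligned_trace(activity.traces, ev.trial_index, ev.time,
                             pre_s, post_s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctr = np.nanmean(np.stack([
                _aligned_trace(activity.traces, j, t, pre_s, post_s)
                for j, t in ev.controls]), axis=0)
        cells[(ev.direction, group)].append(evt - ctr)
    if any(len(v) == 0 for v in cells.values()):
        return None
    times = (np.arange(int(round((pre_s + post_s) * 1000)))
             - int(round(pre_s * 1000))) / 1000.0
    out = {}
    for key, traces in cells.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_trace = np.nanmean(np.stack(traces), axis=0)
        wstats = {}
        for (a, b) in windows:
            sel = (times >= a) & (times < b)
            wstats[(a, b)] = float(np.nanmean(mean_trace[sel]))
        out[key] = {"times": times, "trace": mean_trace, "windows": wstats,
                    "n_events": len(traces)}
    return out


def population_shift_aligned(per_neuron: Sequence[dict],
                             windows: Sequence = DEFAULT_SHIFT_WINDOWS
                             ) -> dict:
    """Average per-neuron shift-aligned results across neurons."""
    per_neuron = [r for r in per_neuron if r is not None]
    if not per_neuron:
        raise ValidationError("no included neurons")
    out = {}
    for key in per_neuron[0]:
        traces = np.stack([r[key]["trace"] for r in per_neuron])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_trace = np.nanmean(traces, axis=0)
        wstats = {w: float(np.mean([r[key]["windows"][w] for r in per_neuron]))
                  for w in [tuple(w) for w in windows]}
        out[key] = {"times": per_neuron[0][key]["times"], "trace": mean_trace,
                    "windows": wstats, "n_neurons": len(per_neuron)}
    return out


# ---------------------------------------------------------------------------
# Lick detection
# ---------------------------------------------------------------------------

def _lick_filter(trace: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """|signal| low-passed with a causal eighth-order 10 Hz Butterworth
    filter (steady-state initial conditions, so no onset transient)."""
    sos = signal.butter(8, 10.0, btype="low", fs=fs, output="sos")
    x = np.abs(np.asarray(trace, dtype=float))
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def lick_threshold(traces: Sequence[np.ndarray],
                   baseline_s: float = 0.4) -> float:
    """Session lick threshold: mean + 2 SD of the pooled filtered baseline
    samples (the first 0.4 s of each correct trial)."""
    n_base = int(round(baseline_s * 1000))
    pool = np.concatenate([_lick_filter(t)[:n_base] for t in traces])
    return float(pool.mean() + 2.0 * pool.std(ddof=0))


def detect_licks(lick: np.ndarray,
                 baseline_traces: Optional[Sequence[np.ndarray]] = None,
                 baseline_s: float = 0.4,
                 threshold: Optional[float] = None) -> np.ndarray:
    """Per-millisecond lick flags for one trial's strain-gauge trace.

    The absolute strain signal is low-pass filtered (eighth-order Butterworth,
    10 Hz cutoff) and compared against a session-level threshold: the mean of
    the filtered baseline samples plus two times their SD.  The baseline pool
    defaults to this trace's own first 0.4 s; pass ``baseline_traces`` (all
    correct trials of the session) or a precomputed ``threshold`` for the
    session-level variant.
    """
    if lick is None:
        raise ValidationError("lick trace absent")
    if threshold is None:
        pool = baseline_traces if baseline_traces is not None else [lick]
        threshold = lick_threshold(pool, baseline_s)
    return _lick_filter(lick) > threshold


# ---------------------------------------------------------------------------
# Behavioral indexes and gaze time courses
# ---------------------------------------------------------------------------

def behavioral_anticipation_indexes(session: NeuronSession,
                                    centers: Optional[dict] = None,
                                    radius: float = GAZE_RADIUS_DEG,
                                    n_perms: int = 20000,
                                    seed: Optional[int] = None
                                    ) -> AnticipationIndexes:
    """Gaze-based anticipation indexes for an information-task session.

    Identical formulas to the neural indexes, but the per-trial value is the
    binary gaze-on-stimulus flag at the *last millisecond* of each analysis
    window (pre-cue, post-cue, pre-outcome); the ROC runs over these binary
    values and no sign normalization is applied.
    """
    if session.task_id == "standard_uncertainty":
        raise ValidationError("behavioral indexes need an information task")
    trials = session.trials
    t_cue = trials[0].t_cue_on
    t_out = trials[0].t_outcome
    last_ms = {
        "precue": int(round(t_cue * 1000)) - 1,
        "postcue": int(round((t_cue + 0.65) * 1000)) - 1,
        "preout": int(round(t_out * 1000)) - 1,
    }
    vals = {k: np.empty(len(trials)) for k in last_ms}
    for i, tr in enumerate(trials):
        center = (centers or {}).get(tr.condition.cs_location,
                                     NOMINAL_CENTERS[tr.condition.cs_location])
        flags = gaze_on_flags(tr, center, radius)
        for k, ms in last_ms.items():
            vals[k][i] = flags[ms]
    return anticipation_indexes_from_values(
        vals["precue"], vals["postcue"], vals["preout"],
        info=np.array([t.condition.cs_kind == "info" for t in trials]),
        uncertain=np.array([t.condition.uncertain for t in trials]),
        reward_prob=np.array([t.condition.reward_prob for t in trials]),
        sign_S=1, n_perms=n_perms, seed=seed,
    )


def gaze_probability_timecourse(sessions: Sequence[NeuronSession],
                                centers: Optional[dict] = None,
                                radius: float = GAZE_RADIUS_DEG) -> dict:
    """P(gaze on stimulus) at each millisecond, per condition.

    Returns ``{condition: (mean, se)}`` where the mean is the across-trial
    average of the on-flag pooled over sessions and the SE is computed across
    sessions (NaN with a single session).
    """
    if not sessions:
        raise ValidationError("need at least one session")
    per_session = {}
    for s in sessions:
        by_cond = {}
        for tr in s.trials:
            center = (centers or {}).get(
                tr.condition.cs_location,
                NOMINAL_CENTERS[tr.condition.cs_location])
            by_cond.setdefault(tr.condition, []).append(
                gaze_on_flags(tr, center, radius))
        for cond, flags in by_cond.items():
            n_ms = min(f.size for f in flags)
            curve = np.stack([f[:n_ms] for f in flags]).mean(axis=0)
            per_session.setdefault(cond, []).append(curve)
    out = {}
    for cond, curves in per_session.items():
        n_ms = min(c.size for c in curves)
        mat = np.stack([c[:n_ms] for c in curves])
        mean = mat.mean(axis=0)
        se = (mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
              if mat.shape[0] > 1 else np.full(n_ms, np.nan))
        out[cond] = (mean, se)
    return out
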