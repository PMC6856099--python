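"""Domain types, invariant checks, and session-bundle I/O.

A *session* is one neuron's worth of trial-structured data: per-trial
condition labels, spike times, 1 kHz gaze samples, optional 1 kHz lick-strain
samples, event times, and reaction times.  All event and spike times are in
seconds relative to CS (conditioned stimulus) onset, which defines time 0 of
every trial; milliseconds appear only as sampling indexes.  All analysis
windows are half-open ``[t_start, t_end)``.

Bundles are plain-text directories: a ``meta.json`` record plus tidy TSV
tables (``trials``, ``spikes``, ``gaze``, optional ``lick``).  Writing is
bit-stable: the same session always produces byte-identical files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TASK_IDS",
    "CS_KINDS",
    "AREAS",
    "CS_LOCATIONS",
    "ValidationError",
    "ParseError",
    "Condition",
    "Trial",
    "NeuronSession",
    "AnalysisWindow",
    "WindowData",
    "window_slice",
    "read_session_bundle",
    "write_session_bundle",
]

TASK_IDS = ("standard_uncertainty", "info", "gaze_contingent_info")
CS_KINDS = ("info", "noinfo", "standard")
AREAS = ("ACC", "icbDS", "Pal")
CS_LOCATIONS = ("left", "right", "center")

#: Reward probabilities used by the provided session generators.
GENERATOR_REWARD_PROBS = (0.0, 0.25, 0.5, 0.75, 1.0)


class ValidationError(ValueError):
    """An invariant of the session data model is violated."""


class ParseError(ValueError):
    """A session bundle on disk is malformed."""


@dataclass(frozen=True, order=True)
class Condition:
    """One task condition: a combination of CS and cue.

    Parameters
    ----------
    task_id:
        One of ``standard_uncertainty``, ``info``, ``gaze_contingent_info``.
    cs_kind:
        ``info`` / ``noinfo`` for information tasks, ``standard`` otherwise.
    reward_prob:
        Reward probability cued by the CS, as a fraction in [0, 1].
    reward_amount:
        Juice amount in mL (>= 0).
    cue_id:
        Small integer identifying the cue; 0 means the task has no cue epoch.
    cs_location:
        Screen location of the CS.
    """

    task_id: str
    cs_kind: str
    reward_prob: float
    reward_amount: float = 0.25
    cue_id: int = 0
    cs_location: str = "center"

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValidationError(f"unknown task_id {self.task_id!r}")
        if self.cs_kind not in CS_KINDS:
            raise ValidationError(f"unknown cs_kind {self.cs_kind!r}")
        if not 0.0 <= self.reward_prob <= 1.0:
            raise ValidationError("reward_prob must be in [0, 1]")
        if self.reward_amount < 0:
            raise ValidationError("reward_amount must be >= 0")
        if self.cs_location not in CS_LOCATIONS:
            raise ValidationError(f"unknown cs_location {self.cs_location!r}")
        has_cue_epoch = self.task_id != "standard_uncertainty"
        if has_cue_epoch != (self.cue_id != 0):
            raise ValidationError(
                "cue_id must be 0 iff the task has no cue epoch "
                f"(task_id={self.task_id!r}, cue_id={self.cue_id})"
            )

    @property
    def uncertain(self) -> bool:
        """Whether the CS leaves the reward outcome uncertain (0 < p < 1)."""
        return 0.0 < self.reward_prob < 1.0


@dataclass
class Trial:
    """One behavioral trial, aligned so that CS onset is time 0.

    ``gaze`` holds 1 kHz samples as a ``(n_ms, 3)`` array of
    ``(x_deg, y_deg, blink_flag)``; the sample at row ``i`` covers millisecond
    ``i``.  ``lick`` holds 1 kHz strain samples or is absent.  ``spikes`` are
    sorted ascending spike times in seconds.
    """

    condition: Condition
    duration: float
    t_outcome: float
    spikes: np.ndarray
    gaze: np.ndarray
    t_cue_on: Optional[float] = None
    t_go: Optional[float] = None
    lick: Optional[np.ndarray] = None
    rt: Optional[float] = None

    #: CS onset defines time zero of each trial.
    t_cs_on: float = 0.0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        if self.lick is not None:
            self.lick = np.asarray(self.lick, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValidationError("trial duration must be positive")
        if self.spikes.ndim != 1:
            raise ValidationError("spikes must be a 1-D array of times")
        if np.any(np.diff(self.spikes) < 0):
            raise ValidationError("spike times must be sorted ascending")
        n_ms = int(math.floor(1000.0 * self.duration))
        if self.gaze.ndim != 2 or self.gaze.shape[1] != 3:
            raise ValidationError("gaze must be an (n_ms, 3) array")
        if self.gaze.shape[0] != n_ms:
            raise ValidationError(
                f"gaze sample count {self.gaze.shape[0]} != trial duration in "
                f"ms ({n_ms})"
            )
        if self.lick is not None and self.lick.shape != (n_ms,):
            raise ValidationError("lick must be a 1-D array of n_ms samples")
        if self.t_cue_on is not None:
            if not (0.0 < self.t_cue_on < self.t_outcome):
                raise ValidationError("need 0 < t_cue_on < t_outcome")
        if self.condition.cue_id != 0 and self.t_cue_on is None:
            raise ValidationError("condition has a cue epoch but t_cue_on absent")
        if self.rt is not None and self.rt < 0:
            raise ValidationError("rt must be >= 0")

    @property
    def n_ms(self) -> int:
        return self.gaze.shape[0]

    def anchor_time(self, anchor: str) -> float:
        """Resolve a named anchor event to an absolute trial time."""
        if anchor == "cs_on":
            return self.t_cs_on
        if anchor == "cue_on":
            if self.t_cue_on is None:
                raise ValidationError("trial has no cue epoch (anchor cue_on)")
            return self.t_cue_on
        if anchor == "outcome":
            return self.t_outcome
        raise ValidationError(f"anchor {anchor!r} not resolvable on a trial")


@dataclass
class NeuronSession:
    """All trials recorded from one neuron in one task, plus metadata."""

    neuron_id: str
    area: str
    animal_id: str
    trials: list
    sign_S: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"unknown area {self.area!r}")
        if self.sign_S not in (None, -1, 1):
            raise ValidationError("sign_S must be -1, +1, or unset (None)")
        task_ids = {t.condition.task_id for t in self.trials}
        if len(task_ids) > 1:
            raise ValidationError(f"trials mix task_ids {sorted(task_ids)}")

    @property
    def task_id(self) -> Optional[str]:
        return self.trials[0].condition.task_id if self.trials else None

    def conditions(self) -> list:
        """Distinct conditions, in sorted (stable) order."""
        return sorted({t.condition for t in self.trials})

    def trials_where(self, **kwargs) -> list:
        """Trials whose condition fields match all given keyword values."""
        out = []
        for t in self.trials:
            if all(getattr(t.condition, k) == v for k, v in kwargs.items()):
                out.append(t)
        return out


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window ``[t_start, t_end)`` relative to an anchor event."""

    t_start: float
    t_end: float
    anchor: str = "cs_on"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            # permit the degenerate empty window [a, a)
            if self.t_start != self.t_end:
                raise ValidationError("window must have t_start <= t_end")
        if self.anchor not in ("cs_on", "cue_on", "outcome", "gaze_shift"):
            raise ValidationError(f"unknown anchor {self.anchor!r}")


@dataclass
class WindowData:
    """Spike times and gaze samples selected by :func:`window_slice`."""

    spikes: np.ndarray      # absolute trial times, within the window
    gaze: np.ndarray        # (k, 3) gaze samples whose ms fall in the window
    ms_start: int           # first ms index included
    ms_stop: int            # one past the last ms index included
    t_start: float          # absolute window start (s)
    t_end: float            # absolute window end (s)


def window_slice(trial: Trial, w: AnalysisWindow,
                 anchor_time: Optional[float] = None) -> WindowData:
    """Select the spikes and gaze samples of ``trial`` inside window ``w``.

    The selection is half-open after anchoring: a spike at exactly the window
    end is excluded.  ``anchor_time`` must be supplied for the ``gaze_shift``
    anchor (event times are trial-specific); for the named event anchors it is
    resolved from the trial.
    """
    if anchor_time is None:
        if w.anchor == "gaze_shift":
            raise ValidationError("gaze_shift anchor requires anchor_time")
        anchor_time = trial.anchor_time(w.anchor)
    t0 = anchor_time + w.t_start
    t1 = anchor_time + w.t_end
    spikes = trial.spikes[(trial.spikes >= t0) & (trial.spikes < t1)]
    # gaze sample i covers millisecond i, i.e. time i/1000
    ms_start = max(0, int(math.ceil(t0 * 1000.0 - 1e-9)))
    ms_stop = min(trial.n_ms, int(math.ceil(t1 * 1000.0 - 1e-9)))
    ms_stop = max(ms_start, ms_stop)
    return WindowData(spikes=spikes, gaze=trial.gaze[ms_start:ms_stop],
                      ms_start=ms_start, ms_stop=ms_stop, t_start=t0, t_end=t1)


# ---------------------------------------------------------------------------
# Session-bundle I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # exact float64 round trip

_TRIAL_COLUMNS = [
    "trial_id", "task_id", "cs_kind", "reward_prob", "reward_amount",
    "cue_id", "cs_location", "duration", "t_cue_on", "t_outcome", "t_go",
    "rt",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return _FLOAT_FMT % x
    return str(x)


def write_session_bundle(session: NeuronSession, path: str) -> None:
    """Write ``session`` as a plain-text bundle directory at ``path``.

    The bundle contains ``meta.json``, ``trials.tsv``, ``spikes.tsv``,
    ``gaze.tsv`` and, only if any trial carries a lick trace, ``lick.tsv``.
    Output is byte-stable for identical input.
    """
    os.makedirs(path, exist_ok=True)
    meta = {
        "neuron_id": session.neuron_id,
        "area": session.area,
        "animal_id": session.animal_id,
        "sign_S": session.sign_S,
        "n_trials": len(session.trials),
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")

    trial_rows = []
    spike_rows = []
    gaze_rows = []
    lick_rows = []
    for i, tr in enumerate(session.trials):
        c = tr.condition
        trial_rows.append("\t".join([
            str(i), c.task_id, c.cs_kind, _fmt(c.reward_prob),
            _fmt(c.reward_amount), str(c.cue_id), c.cs_location,
            _fmt(tr.duration), _fmt(tr.t_cue_on), _fmt(tr.t_outcome),
            _fmt(tr.t_go), _fmt(tr.rt),
        ]))
        for t in tr.spikes:
            spike_rows.append(f"{i}\t{_FLOAT_FMT % t}")
        for ms in range(tr.n_ms):
            x, y, b = tr.gaze[ms]
            gaze_rows.append(
                f"{i}\t{ms}\t{_FLOAT_FMT % x}\t{_FLOAT_FMT % y}\t{int(b)}"
            )
        if tr.lick is not None:
            for ms in range(tr.n_ms):
                lick_rows.append(f"{i}\t{ms}\t{_FLOAT_FMT % tr.lick[ms]}")

    def _write_table(name: str, header: str, rows: list) -> None:
        with open(os.path.join(path, name), "w") as fh:
            fh.write(header + "\n")
            fh.write("\n".join(rows))
            if rows:
                fh.write("\n")

    _write_table("trials.tsv", "\t".join(_TRIAL_COLUMNS), trial_rows)
    _write_table("spikes.tsv", "trial_id\tt", spike_rows)
    _write_table("gaze.tsv", "trial_id\tms\tx\ty\tblink", gaze_rows)
    if lick_rows:
        _write_table("lick.tsv", "trial_id\tms\tv", lick_rows)
    elif os.path.exists(os.path.join(path, "lick.tsv")):
        os.remove(os.path.join(path, "lick.tsv"))


def _read_table(path: str, name: str, required: bool = True):
    fpath = os.path.join(path, name)
    if not os.path.exists(fpath):
        if required:
            raise ParseError(f"bundle is missing table {name!r}")
        return None
    try:
        return pd.read_csv(fpath, sep="\t", float_precision="round_trip")
    except Exception as exc:  # malformed table
        raise ParseError(f"cannot parse table {name!r}: {exc}") from exc


def read_session_bundle(path: str) -> NeuronSession:
    """Read and fully validate a session bundle written by
    :func:`write_session_bundle`."""
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise ParseError("bundle is missing meta.json")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except Exception as exc:
        raise ParseError(f"cannot parse meta.json: {exc}") from exc

    trials_df = _read_table(path, "trials.tsv")
    spikes_df = _read_table(path, "spikes.tsv")
    gaze_df = _read_table(path, "gaze.tsv")
    lick_df = _read_table(path, "lick.tsv", required=False)

    for col in _TRIAL_COLUMNS:
        if col not in trials_df.columns:
            raise ParseError(f"trials table is missing column {col!r}")

    spikes_by_trial = {k: g["t"].to_numpy(float)
                       for k, g in spikes_df.groupby("trial_id")}
    gaze_by_trial = dict(tuple(gaze_df.groupby("trial_id")))
    lick_by_trial = (dict(tuple(lick_df.groupby("trial_id")))
                     if lick_df is not None else {})

    def _opt(v):
        return None if pd.isna(v) else float(v)

    trials = []
    for _, row in trials_df.iterrows():
        tid = int(row["trial_id"])
        try:
            cond = Condition(
                task_id=str(row["task_id"]), cs_kind=str(row["cs_kind"]),
                reward_prob=float(row["reward_prob"]),
                reward_amount=float(row["reward_amount"]),
                cue_id=int(row["cue_id"]),
                cs_location=str(row["cs_location"]),
            )
            g = gaze_by_trial.get(tid)
            if g is None:
                gaze = np.empty((0, 3))
            else:
                g = g.sort_values("ms")
                if not np.array_equal(g["ms"].to_numpy(),
                                      np.arange(len(g))):
                    raise ValidationError(
                        f"gaze ms indexes of trial {tid} are not 0..n-1")
                gaze = g[["x", "y", "blink"]].to_numpy(float)
            lick = None
            if tid in lick_by_trial:
                lg = lick_by_trial[tid].sort_values("ms")
                lick = lg["v"].to_numpy(float)
            trial = Trial(
                condition=cond, duration=float(row["duration"]),
                t_outcome=float(row["t_outcome"]),
                spikes=spikes_by_trial.get(tid, np.empty(0)),
                gaze=gaze, t_cue_on=_opt(row["t_cue_on"]),
                t_go=_opt(row["t_go"]), lick=lick, rt=_opt(row["rt"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"trial {tid}: {exc}") from exc
        trials.append(trial)

    sign = meta.get("sign_S")
    return NeuronSession(
        neuron_id=str(meta.get("neuron_id", "")),
        area=str(meta.get("area", "")),
        animal_id=str(meta.get("animal_id", "")),
        trials=trials,
        sign_S=int(sign) if sign is not None else None,
    )
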