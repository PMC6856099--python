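"""Reaction-time processing and perturbation statistics.

The behavioral readout of information seeking is the Infobias Index::

    Infobias = (Noinfo RT - Info RT) / (Noinfo RT + Info RT)

computed from mean reaction times; positive values mean faster gaze shifts
toward the information-predictive CS.  Inactivation effects are quantified as
the post-minus-pre change in the index (per session, per CS laterality) and
tested with permutation tests that reshuffle each session's trials between
the pre- and post-injection epochs.  Normalized-RT analyses z-score RTs
within each session and CS location, then contrast Info/Noinfo RT changes
between areas (the hypothesized icbDS-slows-Info / Pal-speeds-Noinfo pattern
versus its orthogonal counterpart).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_session import ValidationError

__all__ = [
    "InactivationSession",
    "derive_cs_side",
    "filter_rts",
    "infobias_index",
    "session_infobias",
    "InfobiasResult",
    "infobias_change_test",
    "normalize_rts",
    "rt_epoch_tests",
    "delta_rt_contrasts",
]

INACTIVATION_AREAS = ("icbDS", "Pal", "control_saline", "control_sham")
TRIAL_COLUMNS = ("epoch", "cs_type", "cs_side", "rt", "rt_online")


@dataclass
class InactivationSession:
    """Pre/post-injection reaction-time table for one behavioral session.

    ``trials`` is a DataFrame with columns ``epoch`` (pre|post), ``cs_type``
    (info|noinfo), ``cs_side`` (contra|ipsi, relative to the injection),
    ``rt`` and ``rt_online`` in seconds.
    """

    session_id: str
    animal_id: str
    area: str
    injection_side: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.area not in INACTIVATION_AREAS:
            raise ValidationError(f"unknown area {self.area!r}")
        if self.injection_side not in ("left", "right"):
            raise ValidationError("injection_side must be left or right")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValidationError(f"trials table missing columns {missing}")
        if (self.trials["rt"] <= 0).any():
            raise ValidationError("rt must be positive")

    @property
    def is_inactivation(self) -> bool:
        return self.area in ("icbDS", "Pal")


def derive_cs_side(cs_screen_side: str, injection_side: str) -> str:
    """Contra/ipsi laterality of a CS given its screen side and the
    injection hemisphere."""
    if cs_screen_side not in ("left", "right"):
        raise ValidationError("cs_screen_side must be left or right")
    return "contra" if cs_screen_side != injection_side else "ipsi"


def filter_rts(session: InactivationSession,
               max_disagreement_s: float = 0.2) -> InactivationSession:
    """Keep trials whose offline and online RTs roughly agree (within 0.2 s)."""
    t = session.trials
    keep = (t["rt"] - t["rt_online"]).abs() <= max_disagreement_s
    return replace(session, trials=t[keep].reset_index(drop=True))


def infobias_index(rts_info: Sequence, rts_noinfo: Sequence) -> float:
    """(mean Noinfo RT - mean Info RT) / (mean Noinfo RT + mean Info RT).

    Positive values indicate a response bias favoring the Info CS.  Returns
    NaN if either cell is empty.
    """
    a = np.asarray(rts_info, dtype=float)
    b = np.asarray(rts_noinfo, dtype=float)
    if a.size == 0 or b.size == 0:
        return math.nan
    return float((b.mean() - a.mean()) / (b.mean() + a.mean()))


def session_infobias(session: InactivationSession) -> dict:
    """Infobias Index for each (epoch, laterality) cell of one session."""
    out = {}
    t = session.trials
    for epoch in ("pre", "post"):
        for side in ("contra", "ipsi"):
            cell = t[(t["epoch"] == epoch) & (t["cs_side"] == side)]
            out[(epoch, side)] = infobias_index(
                cell.loc[cell["cs_type"] == "info", "rt"],
                cell.loc[cell["cs_type"] == "noinfo", "rt"])
    return out


@dataclass
class InfobiasResult:
    """Mean post-minus-pre change in Infobias Index and its permutation p."""

    mean_change: float
    p: float
    n_perms: int
    per_session: np.ndarray
    laterality: str


def _session_arrays(session: InactivationSession, laterality: str):
    t = session.trials[session.trials["cs_side"] == laterality]
    rt = t["rt"].to_numpy(float)
    is_info = (t["cs_type"] == "info").to_numpy()
    is_pre = (t["epoch"] == "pre").to_numpy()
    return rt, is_info, int(is_pre.sum())


def _change_from_assignment(rt, is_info, pre_mask) -> float:
    """Infobias change given a boolean pre-epoch assignment (post = ~pre)."""
    def idx(mask):
        info = rt[mask & is_info]
        noinfo = rt[mask & ~is_info]
        if info.size == 0 or noinfo.size == 0:
            return math.nan
        return (noinfo.mean() - info.mean()) / (noinfo.mean() + info.mean())
    return idx(~pre_mask) - idx(pre_mask)


def infobias_change_test(sessions: Sequence[InactivationSession],
                         laterality: str = "contra",
                         n_perms: int = 100000,
                         seed: Optional[int] = None,
                         animal_weighting: bool = False,
                         animal_weights: Optional[dict] = None,
                         chunk: int = 20000) -> InfobiasResult:
    """Permutation test of the mean change in Infobias Index.

    The null reshuffles each session's trials between the pre and post
    epochs, preserving per-epoch trial counts; the two-tailed p-value
    compares the observed mean (optionally animal-weighted) change to the
    permutation distribution.  With ``animal_weighting``, per-animal mean
    changes are averaged with weights equal to the number of inactivation
    sessions each animal contributed (pass ``animal_weights`` explicitly for
    control-session data sets).
    """
    if not sessions:
        raise ValidationError("need at least one session")
    if n_perms < 1000:
        import warnings
        warnings.warn("n_perms < 1000 gives a coarse p-value resolution")
    rng = np.random.default_rng(seed)
    data = [_session_arrays(s, laterality) for s in sessions]
    animals = [s.animal_id for s in sessions]

    if animal_weighting:
        if animal_weights is None:
            animal_weights = {}
            for s in sessions:
                if s.is_inactivation:
                    animal_weights[s.animal_id] = \
                        animal_weights.get(s.animal_id, 0) + 1
        if not animal_weights:
            raise ValidationError(
                "animal_weighting requires inactivation sessions or explicit "
                "animal_weights")

    import warnings as _warnings

    def _combine(changes: np.ndarray) -> float:
        # a degenerate permutation can empty a cell (NaN change); such
        # sessions drop out of the mean for that permutation
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            if not animal_weighting:
                return float(np.nanmean(changes))
            tot_w, acc = 0.0, 0.0
            for a in set(animals):
                w = animal_weights.get(a, 0.0)
                if w <= 0:
                    continue
                vals = [c for c, an in zip(changes, animals) if an == a]
                acc += w * float(np.nanmean(vals))
                tot_w += w
            return acc / tot_w

    true_changes = np.array([
        _change_from_assignment(rt, info, _true_pre(rt, n_pre))
        for (rt, info, n_pre) in data
    ])
    true_stat = _combine(true_changes)

    n_ge = 0
    done = 0
    while done < n_perms:
        b = min(chunk, n_perms - done)
        perm_changes = np.empty((b, len(data)))
        for si, (rt, info, n_pre) in enumerate(data):
            n = rt.size
            u = rng.random((b, n))
            order = np.argsort(u, axis=1)
            pre = np.zeros((b, n), dtype=bool)
            np.put_along_axis(pre, order[:, :n_pre], True, axis=1)
            post = ~pre
            i_rt = rt * info
            n_rt = rt * ~info
            def cellmean(mask, v, cnt_vec):
                s = mask @ v
                c = mask @ cnt_vec
                with np.errstate(invalid="ignore", divide="ignore"):
                    return s / c
            info_f = info.astype(float)
            noinfo_f = (~info).astype(float)
            m_pre_i = cellmean(pre, i_rt, info_f)
            m_pre_n = cellmean(pre, n_rt, noinfo_f)
            m_post_i = cellmean(post, i_rt, info_f)
            m_post_n = cellmean(post, n_rt, noinfo_f)
            idx_pre = (m_pre_n - m_pre_i) / (m_pre_n + m_pre_i)
            idx_post = (m_post_n - m_post_i) / (m_post_n + m_post_i)
            perm_changes[:, si] = idx_post - idx_pre
        for row in perm_changes:
            if abs(_combine(row)) >= abs(true_stat) - 1e-12:
                n_ge += 1
        done += b
    p = (1.0 + n_ge) / (n_perms + 1.0)
    return InfobiasResult(mean_change=true_stat, p=p, n_perms=n_perms,
                          per_session=true_changes, laterality=laterality)


def _true_pre(rt: np.ndarray, n_pre: int) -> np.ndarray:
    pre = np.zeros(rt.size, dtype=bool)
    pre[:n_pre] = True
    return pre


def normalize_rts(sessions: Sequence[InactivationSession]
                  ) -> list:
    """Z-score RTs within each (session, CS laterality), pooled across epochs
    and CS types; adds an ``rt_z`` column."""
    out = []
    for s in sessions:
        t = s.trials.copy()
        t["rt_z"] = np.nan
        for side in t["cs_side"].unique():
            mask = t["cs_side"] == side
            vals = t.loc[mask, "rt"]
            if len(vals) < 2:
                raise ValidationError(
                    f"session {s.session_id}: <2 RTs for side {side}")
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValidationError(
                    f"session {s.session_id}: zero RT SD for side {side}")
            t.loc[mask, "rt_z"] = (vals - vals.mean()) / sd
        out.append(replace(s, trials=t))
    return out


def _pooled_contra(sessions: Sequence[InactivationSession]) -> pd.DataFrame:
    frames = []
    for s in sessions:
        t = s.trials
        if "rt_z" not in t.columns:
            raise ValidationError("run normalize_rts first")
        t = t[t["cs_side"] == "contra"].copy()
        t["session_id"] = s.session_id
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def rt_epoch_tests(sessions: Sequence[InactivationSession]) -> dict:
    """Pre-vs-post RT statistics on normalized contralateral RTs.

    Returns per-CS-type rank-sum p-values and mean RT changes, plus the
    interaction term of a two-way fixed-effects ANOVA (type-II sums of
    squares) with factors CS type and epoch.
    """
    from scipy import stats as sps
    from statsmodels.stats.anova import anova_lm

    df = _pooled_contra(sessions)
    out = {}
    for cs in ("info", "noinfo"):
        pre = df[(df["cs_type"] == cs) & (df["epoch"] == "pre")]["rt_z"]
        post = df[(df["cs_type"] == cs) & (df["epoch"] == "post")]["rt_z"]
        if len(pre) == 0 or len(post) == 0:
            raise ValidationError(f"empty pre/post cell for {cs}")
        res = sps.mannwhitneyu(pre, post, alternative="two-sided",
                               method="asymptotic")
        out[cs] = {"p": float(res.pvalue),
                   "change": float(post.mean() - pre.mean())}
    model = smf.ols("rt_z ~ C(cs_type) * C(epoch)", data=df).fit()
    table = anova_lm(model, typ=2)
    inter = table.loc["C(cs_type):C(epoch)"]
    out["anova_interaction"] = {
        "F": float(inter["F"]), "p": float(inter["PR(>F)"]),
        "df": (int(inter["df"]), int(table.loc["Residual", "df"])),
    }
    return out


def _area_cell_means(df: pd.DataFrame) -> dict:
    """Mean normalized contralateral RT per (cs_type, epoch)."""
    out = {}
    for cs in ("info", "noinfo"):
        for ep in ("pre", "post"):
            cell = df[(df["cs_type"] == cs) & (df["epoch"] == ep)]["rt_z"]
            if len(cell) == 0:
                raise ValidationError(f"empty cell ({cs}, {ep})")
            out[(cs, ep)] = float(cell.mean())
    return out


def _contrasts(m_icbds: dict, m_pal: dict) -> tuple:
    d_icbds = 0.5 * (m_icbds[("info", "post")] - m_icbds[("info", "pre")]) \
        + 0.5 * (m_icbds[("noinfo", "post")] - m_icbds[("noinfo", "pre")])
    d_pal = 0.5 * (m_pal[("info", "post")] - m_pal[("info", "pre")]) \
        + 0.5 * (m_pal[("noinfo", "post")] - m_pal[("noinfo", "pre")])
    hyp = (m_icbds[("info", "post")] - m_icbds[("info", "pre")]) \
        - (m_pal[("noinfo", "post")] - m_pal[("noinfo", "pre")])
    orth = (m_icbds[("noinfo", "post")] - m_icbds[("noinfo", "pre")]) \
        - (m_pal[("info", "post")] - m_pal[("info", "pre")])
    return d_icbds, d_pal, hyp, orth


def delta_rt_contrasts(icbds_sessions: Sequence[InactivationSession],
                       pal_sessions: Sequence[InactivationSession],
                       n_perms: int = 2000,
                       seed: Optional[int] = None) -> dict:
    """Between-area contrasts of normalized-RT changes.

    Computes each area's overall post-minus-pre change in mean normalized
    contralateral RT (averaged over Info and Noinfo CSs), the *hypothesized*
    contrast (icbDS slowing Info-CS RTs combined with Pal speeding Noinfo-CS
    RTs) and the *orthogonal* contrast (icbDS/Noinfo combined with Pal/Info).
    Two-tailed permutation p-values reshuffle each session's trials between
    epochs.
    """
    if not icbds_sessions or not pal_sessions:
        raise ValidationError("need sessions for both areas")
    rng = np.random.default_rng(seed)
    df_i = _pooled_contra(icbds_sessions)
    df_p = _pooled_contra(pal_sessions)
    d_i, d_p, hyp, orth = _contrasts(_area_cell_means(df_i),
                                     _area_cell_means(df_p))
    true_stats = np.array([d_i - d_p, hyp, orth])

    def _perm_df(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for sid in out["session_id"].unique():
            idx = out.index[out["session_id"] == sid]
            ep = out.loc[idx, "epoch"].to_numpy()
            out.loc[idx, "epoch"] = ep[rng.permutation(ep.size)]
        return out

    n_ge = np.zeros(3)
    for _ in range(n_perms):
        pi, pp = _perm_df(df_i), _perm_df(df_p)
        di, dp, h, o = _contrasts(_area_cell_means(pi), _area_cell_means(pp))
        stats_perm = np.array([di - dp, h, o])
        n_ge += np.abs(stats_perm) >= np.abs(true_stats) - 1e-12
    p = (1.0 + n_ge) / (n_perms + 1.0)
    return {
        "delta_overall_icbds": d_i, "delta_overall_pal": d_p,
        "p_overall_diff": float(p[0]),
        "delta_hypothesized": hyp, "p_hypothesized": float(p[1]),
        "delta_orthogonal": orth, "p_orthogonal": float(p[2]),
        "n_perms": n_perms,
    }
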