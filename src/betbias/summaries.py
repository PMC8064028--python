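"""Behavioural summaries and single-case inference.

Win-stay/lose-switch proportions and the 2x2 bet cell means, the per-subject
win-stay betting interaction, repeated-measures ANOVA over the four cells,
single-case patient-versus-controls Z tests, winnings binned by bet level,
and the percentile sliding-window curves used to visualise value effects.

Previous-trial conditioning never crosses a block boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "arcsine_transform", "winstay_summary", "cohort_winstay_table",
    "bet_anova_2x2", "single_case_z", "winnings_by_bet_bin",
    "quantile_sliding_curve", "residualized_prev_bet_curve",
]

_CELLS = ["win_stay", "win_switch", "lose_stay", "lose_switch"]


def arcsine_transform(p) -> np.ndarray | float:
    """Variance-stabilizing arcsin(sqrt(p)) for proportions, range [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def winstay_summary(session: pd.DataFrame) -> pd.Series:
    """Per-subject win-stay/lose-switch row.

    Stay proportions conditioned on the previous trial's outcome (within
    block); mean bet in each of the four previous-win x stay cells; the
    interaction term is the 2x2 double difference of cell mean bets, halved:
    ``([win_stay + lose_switch] - [win_switch + lose_stay]) / 2``.  Positive
    values mean betting more on win-then-stay or lose-then-switch trials.
    Empty cells leave the affected fields missing (logged).
    """
    stay = session["stay"].to_numpy(dtype=float)
    bet = session["bet_level"].to_numpy(dtype=float)
    reward = session["reward"].to_numpy(dtype=float)
    prev_win = np.full(len(session), np.nan)
    prev_win[1:] = reward[:-1]
    ok = ~np.isnan(stay)  # stay defined <=> previous trial in same block
    if not ok.any():
        raise ValueError("no trials with a defined previous trial")

    out: dict[str, float] = {"subject_id": session["subject_id"].iloc[0],
                             "group_label": session["group_label"].iloc[0]}
    for label, w in (("after_win", 1.0), ("after_loss", 0.0)):
        m = ok & (prev_win == w)
        if m.any():
            p = float(np.mean(stay[m] == 1.0))
            out[f"p_stay_{label}"] = p
            out[f"arcsine_stay_{label}"] = arcsine_transform(p)
        else:
            out[f"p_stay_{label}"] = np.nan
            out[f"arcsine_stay_{label}"] = np.nan
            logger.warning("subject %s: no trials %s", out["subject_id"], label)

    cells = {}
    for name, w, st in (("win_stay", 1.0, 1.0), ("win_switch", 1.0, -1.0),
                        ("lose_stay", 0.0, 1.0), ("lose_switch", 0.0, -1.0)):
        m = ok & (prev_win == w) & (stay == st)
        cells[name] = float(bet[m].mean()) if m.any() else np.nan
        out[f"mean_bet_{name}"] = cells[name]
    if all(np.isfinite(v) for v in cells.values()):
        out["interaction_term"] = 0.5 * (
            (cells["win_stay"] + cells["lose_switch"])
            - (cells["win_switch"] + cells["lose_stay"]))
    else:
        out["interaction_term"] = np.nan
        logger.warning("subject %s: empty 2x2 cell, interaction undefined",
                       out["subject_id"])
    return pd.Series(out)


def cohort_winstay_table(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """One win-stay summary row per subject."""
    return pd.DataFrame([winstay_summary(s) for s in sessions])


def bet_anova_2x2(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on the four cell mean bets.

    ``table`` is a cohort win-stay table.  Effects: previous win, stay, and
    their interaction, each tested against its own subject interaction
    (within-subject contrasts, invariant to per-subject bet offsets).
    Subjects with any missing cell are excluded.  Degenerate effects with
    zero numerator variance report F = 0.
    """
    cols = [f"mean_bet_{c}" for c in _CELLS]
    full = table.dropna(subset=cols)
    n_drop = len(table) - len(full)
    if n_drop:
        logger.warning("bet_anova_2x2: %d subjects dropped (missing cells)", n_drop)
    if len(full) < 2:
        raise ValueError("need >= 2 subjects with complete cells")
    long = full.melt(id_vars="subject_id", value_vars=cols,
                     var_name="cell", value_name="bet")
    long["prev_win"] = long["cell"].str.contains("win_").map({True: "win", False: "loss"})
    long["stay"] = long["cell"].str.contains("_stay").map({True: "stay", False: "switch"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 F for flat data
        aov = pg.rm_anova(data=long, dv="bet", within=["prev_win", "stay"],
                          subject="subject_id", detailed=True)
    out = aov.rename(columns={"Source": "effect", "p_unc": "p", "p-unc": "p"})[
        ["effect", "SS", "ddof1", "ddof2", "F", "p"]].copy()
    # 0/0 effects (all subjects identical cells) are no evidence: F = 0
    degen = out["SS"].abs() < 1e-12
    out.loc[degen, "F"] = 0.0
    out.loc[degen, "p"] = 1.0
    return out


def single_case_z(x: float, control_mean: float, control_sd: float,
                  method: str = "z", n_controls: int | None = None,
                  ) -> tuple[float, float]:
    """Compare one patient's statistic to a control sample.

    ``method='z'`` (default): plain Z = (x - mean)/sd with a two-tailed
    normal p.  ``method='crawford'``: Crawford-Howell single-case t, with the
    sd inflated by sqrt((n+1)/n) and a t(n-1) reference (requires
    ``n_controls``).
    """
    if control_sd <= 0:
        raise ValueError("control_sd must be > 0")
    if method == "z":
        z = (x - control_mean) / control_sd
        return float(z), float(2.0 * stats.norm.sf(abs(z)))
    if method == "crawford":
        if n_controls is None or n_controls < 2:
            raise ValueError("crawford method requires n_controls >= 2")
        t = (x - control_mean) / (control_sd * np.sqrt((n_controls + 1) / n_controls))
        return float(t), float(2.0 * stats.t.sf(abs(t), n_controls - 1))
    raise ValueError(f"unknown method {method!r}")


def winnings_by_bet_bin(session: pd.DataFrame) -> pd.Series:
    """Mean signed winnings at each ordinal bet level 1-5; unused levels NaN."""
    if len(session) == 0:
        raise ValueError("empty session")
    level = np.clip(np.rint(session["bet_level"].to_numpy(dtype=float)), 1, 5)
    signed = ((2.0 * session["reward"].to_numpy(dtype=float) - 1.0)
              * session["bet_money"].to_numpy(dtype=float))
    out = pd.Series(np.nan, index=pd.RangeIndex(1, 6, name="bet_level"))
    for lv in range(1, 6):
        m = level == lv
        if m.any():
            out.loc[lv] = float(signed[m].mean())
    return out


def _subject_windows(x: np.ndarray, y: np.ndarray, width: float, step: float,
                     ) -> tuple[np.ndarray, np.ndarray] | None:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    pct = stats.rankdata(x) / len(x) * 100.0 if len(x) else np.array([])
    if len(np.unique(pct)) < 25:
        return None
    starts = np.arange(0.0, 100.0 - width + 1e-9, step)
    cx = np.full(len(starts), np.nan)
    cy = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        m = (pct >= s) & (pct <= s + width)
        if m.any():
            cx[i] = x[m].mean()
            cy[i] = y[m].mean()
    return cx, cy


def quantile_sliding_curve(x_by_subject: dict[str, np.ndarray],
                           y_by_subject: dict[str, np.ndarray],
                           width: float = 25.0, step: float = 1.0,
                           ) -> pd.DataFrame:
    """Sliding percentile-window curve, averaged across subjects.

    For each subject, ``y`` is averaged within each ``width``-percentile
    window of that subject's ``x``, stepped in ``step``-percent quantile
    increments; the curve's x-coordinate is the mean of per-subject bin
    centres.  Subjects with fewer than 25 distinct percentile positions are
    dropped (logged).  Returns bin, x, y_mean, y_sem, n_subjects.
    """
    xs, ys = [], []
    for sid in x_by_subject:
        res = _subject_windows(np.asarray(x_by_subject[sid], dtype=float),
                               np.asarray(y_by_subject[sid], dtype=float),
                               width, step)
        if res is None:
            logger.warning("subject %s dropped from curve: too few distinct "
                           "percentile positions", sid)
            continue
        xs.append(res[0])
        ys.append(res[1])
    if not xs:
        raise ValueError("no subject has enough data for the curve")
    X = np.vstack(xs)
    Y = np.vstack(ys)
    n = np.sum(np.isfinite(Y), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        y_mean = np.nanmean(Y, axis=0)
        y_sem = np.nanstd(Y, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        x_mean = np.nanmean(X, axis=0)
    return pd.DataFrame({"bin": np.arange(len(y_mean)), "x": x_mean,
                         "y_mean": y_mean, "y_sem": y_sem, "n_subjects": n})


def residualized_prev_bet_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Previous-bet bias after factoring out the chosen-value effect.

    Per subject, the bet is regressed on the z-scored chosen value and the
    residuals are averaged by the previous trial's ordinal bet level (1-5);
    rows are group x level with across-subject mean and standard error.
    """
    rows = []
    for sid, sub in table.groupby("subject"):
        d = sub.dropna(subset=["bet", "q_chosen", "prev_bet_level"])
        if len(d) < 3 or d["q_chosen"].std(ddof=0) < 1e-12:
            logger.warning("subject %s dropped from residual curve", sid)
            continue
        res = smf.ols("bet ~ q_chosen", data=d).fit()
        d = d.assign(resid=res.resid)
        for lv, grp in d.groupby("prev_bet_level"):
            rows.append({"group": d["group"].iloc[0], "subject": sid,
                         "prev_bet_level": int(lv),
                         "resid_mean": float(grp["resid"].mean())})
    per_sub = pd.DataFrame(rows)
    if per_sub.empty:
        raise ValueError("no usable subjects for residual curve")
    agg = (per_sub.groupby(["group", "prev_bet_level"])["resid_mean"]
           .agg(resid_mean="mean", resid_sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                n_subjects="count").reset_index())
    return agg
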