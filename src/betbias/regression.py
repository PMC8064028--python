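"""Trial-level mixed-effects regressions for bets and surprise.

All continuous predictors (chosen value Qc, unchosen value Qu, previous bet,
win indicator R) are z-scored within subject; the stay (+/-1) and patient
(0/1) indicators are not.  Every model includes a single random intercept
per subject and is estimated by maximum likelihood (not REML) so BICs are
comparable across fixed-effect structures.  Fixed effects are reported as
t statistics with residual degrees of freedom (rows minus fixed effects).

Model specifications (lme4-style formulas, ``(1|subject)`` implied):

====  ==========================================================
M1    bet ~ 1 + Qc
M2    bet ~ 1 + Qc + prev_bet
M3    bet ~ 1 + Qc + prev_bet + stay + stay:prev_bet
M4    bet ~ 1 + Qc + Qu
M5    bet ~ (1 + Qc + prev_bet) * patient
M5u   bet ~ (1 + Qc + Qu) * patient
S1    surprise ~ 1 + R * Qc
S2    surprise ~ (1 + R * Qc) * patient
====  ==========================================================

Missing data (block-initial previous bets, pre-onset surprise) are removed
listwise per model; row counts are logged so exclusions stay auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_SPECS", "MixedFitResult",
    "prepare_predictors", "fit_bet_model", "fit_surprise_model",
    "compare_bic", "results_to_csv", "results_report",
]

#: formula and the table columns each model needs (response first)
MODEL_SPECS: dict[str, tuple[str, list[str]]] = {
    "M1": ("bet ~ q_chosen", ["bet", "q_chosen"]),
    "M2": ("bet ~ q_chosen + prev_bet", ["bet", "q_chosen", "prev_bet"]),
    "M3": ("bet ~ q_chosen + prev_bet + stay + stay:prev_bet",
           ["bet", "q_chosen", "prev_bet", "stay"]),
    "M4": ("bet ~ q_chosen + q_unchosen", ["bet", "q_chosen", "q_unchosen"]),
    "M5": ("bet ~ (q_chosen + prev_bet) * patient",
           ["bet", "q_chosen", "prev_bet", "patient"]),
    "M5u": ("bet ~ (q_chosen + q_unchosen) * patient",
            ["bet", "q_chosen", "q_unchosen", "patient"]),
    "S1": ("surprise ~ reward * q_chosen", ["surprise", "reward", "q_chosen"]),
    "S2": ("surprise ~ reward * q_chosen * patient",
           ["surprise", "reward", "q_chosen", "patient"]),
}


@dataclass
class MixedFitResult:
    """One fitted regression specification.

    ``fixed_effects`` has one row per term: estimate, se, t, df, p.
    ``singular`` marks a fit whose random-intercept variance collapsed to the
    boundary (reported, never silently dropped).
    """

    name: str
    formula: str
    fixed_effects: pd.DataFrame
    re_var: float
    resid_var: float
    llf: float
    bic: float
    n_rows: int
    n_subjects: int
    singular: bool = False
    converged: bool = True

    def estimate(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


def _zscore_sub(x: pd.Series) -> tuple[pd.Series, bool]:
    """Within-subject population z-score of the non-missing entries.

    Zero-variance columns are set to 0 and flagged."""
    v = x.astype(float)
    m = v.mean()
    sd = v.std(ddof=0)
    if not np.isfinite(sd) or sd < 1e-12:
        return v * 0.0, True
    return (v - m) / sd, False


def prepare_predictors(sessions: list[pd.DataFrame],
                       value_traces: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                       min_trials: int = 3) -> pd.DataFrame:
    """Build the trial-level regression table.

    ``value_traces`` maps subject id to (q_chosen, q_unchosen) arrays aligned
    with that subject's trials (typically from :func:`betbias.rwmodel.fit_rw`);
    if ``None`` the generative ``q_*_gen`` columns of synthetic sessions are
    used.  Output columns ``q_chosen``, ``q_unchosen``, ``prev_bet`` and
    ``reward`` are z-scored within subject; ``stay`` stays +/-1, ``patient``
    is 0/1 (any non-control group).  ``prev_bet`` is the bet on the
    immediately preceding trial within the same block (missing on
    block-initial trials); ``prev_bet_level`` keeps the raw ordinal level of
    that bet for binned summaries.  Zero-variance flags are collected in
    ``table.attrs['zero_variance']``.
    """
    rows = []
    flags: list[tuple[str, str]] = []
    for s in sessions:
        sid = str(s["subject_id"].iloc[0])
        n = len(s)
        if n < min_trials:
            logger.warning("subject %s excluded: only %d trials", sid, n)
            continue
        if value_traces is not None:
            if sid not in value_traces:
                raise KeyError(f"no value trace for subject {sid}")
            qc, qu = value_traces[sid]
            if len(qc) != n or len(qu) != n:
                raise ValueError(f"value trace misaligned for subject {sid}")
        else:
            if "q_chosen_gen" not in s.columns:
                raise ValueError(
                    f"subject {sid}: no value traces given and no generative columns")
            qc = s["q_chosen_gen"].to_numpy(dtype=float)
            qu = s["q_unchosen_gen"].to_numpy(dtype=float)

        bet = s["bet_level"].to_numpy(dtype=float)
        block = s["block"].to_numpy()
        prev_bet = np.full(n, np.nan)
        prev_bet[1:] = bet[:-1]
        prev_bet[np.r_[True, block[1:] != block[:-1]]] = np.nan

        df = pd.DataFrame({
            "subject": sid,
            "group": s["group_label"].iloc[0],
            "patient": int(s["group_label"].iloc[0] != "control"),
            "block": block,
            "trial": s["trial"].to_numpy(),
            "bet": bet,
            "surprise": s["surprise"].to_numpy(dtype=float),
            "q_chosen_raw": qc,
            "q_unchosen_raw": qu,
            "q_chosen": qc,
            "q_unchosen": qu,
            "prev_bet": prev_bet,
            "prev_bet_level": np.clip(np.rint(prev_bet), 1, 5),
            "reward": s["reward"].to_numpy(dtype=float),
            "stay": s["stay"].to_numpy(dtype=float),
        })
        for col in ("q_chosen", "q_unchosen", "reward"):
            z, flag = _zscore_sub(df[col])
            df[col] = z
            if flag:
                flags.append((sid, col))
        pv = df["prev_bet"].dropna()
        sd = pv.std(ddof=0)
        if len(pv) == 0 or sd < 1e-12:
            df["prev_bet"] = np.where(df["prev_bet"].isna(), np.nan, 0.0)
            flags.append((sid, "prev_bet"))
        else:
            df["prev_bet"] = (df["prev_bet"] - pv.mean()) / sd
        rows.append(df)
    if not rows:
        raise ValueError("no usable subjects")
    table = pd.concat(rows, ignore_index=True)
    table.attrs["zero_variance"] = flags
    for sid, col in flags:
        logger.warning("subject %s: zero-variance predictor %s set to 0", sid, col)
    return table


def _ols_fallback(formula: str, data: pd.DataFrame, k_re: int = 2):
    """Profiled-likelihood limit when the random intercept and/or residual
    variance hit the boundary: OLS with subject fixed intercepts when the
    formula allows (no between-subject terms), else pooled OLS."""
    between = "patient" in formula
    f = formula if between else formula + " + C(subject)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual data: singular cov
        res = smf.ols(f, data=data).fit()
    keep = [t for t in res.params.index if not t.startswith("C(subject)")]
    return res, keep


def _fit_mixed(name: str, table: pd.DataFrame) -> MixedFitResult:
    formula, cols = MODEL_SPECS[name]
    data = table.dropna(subset=cols).copy()
    n = len(data)
    n_sub = data["subject"].nunique()
    if n == 0:
        raise ValueError(f"model {name}: no complete rows")
    logger.info("model %s: %d rows (%d excluded), %d subjects",
                name, n, len(table) - n, n_sub)

    singular = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data, groups=data["subject"])
            res = md.fit(reml=False)
            fe = res.fe_params
            se = res.bse_fe
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_var = float(res.scale)
        llf = float(res.llf)
        converged = bool(res.converged)
        ok = (np.all(np.isfinite(fe)) and np.all(np.isfinite(se))
              and np.isfinite(llf) and resid_var > 1e-10)
        if re_var < 1e-8:
            singular = True
    except (np.linalg.LinAlgError, ValueError):
        ok = False
    if not ok:
        # degenerate (e.g. noiseless) data: profile out the random intercept
        res, keep = _ols_fallback(formula, data)
        fe = res.params[keep]
        se = res.bse[keep]
        re_var = 0.0
        resid_var = float(res.scale)
        llf = float(res.llf)
        singular = True
        logger.warning("model %s: mixed fit degenerate, subject-intercept OLS "
                       "fallback used", name)

    k = len(fe)
    dof = n - k
    tvals = fe / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    fixed = pd.DataFrame({
        "estimate": fe, "se": se, "t": tvals,
        "df": float(dof), "p": pvals,
    })
    # k fixed effects + random-intercept variance + residual variance
    bic = -2.0 * llf + (k + 2) * np.log(n)
    return MixedFitResult(name=name, formula=formula, fixed_effects=fixed,
                          re_var=re_var, resid_var=resid_var, llf=llf,
                          bic=float(bic), n_rows=n, n_subjects=n_sub,
                          singular=singular, converged=converged)


def fit_bet_model(table: pd.DataFrame, spec: str = "M1") -> MixedFitResult:
    """Fit one of the bet-bias specifications M1..M5/M5u."""
    if spec not in ("M1", "M2", "M3", "M4", "M5", "M5u"):
        raise ValueError(f"unknown bet model spec {spec!r}")
    return _fit_mixed(spec, table)


def fit_surprise_model(table: pd.DataFrame, group_interaction: bool = False,
                       ) -> MixedFitResult:
    """Fit the surprise model (S1), optionally with all patient-group
    interactions (S2)."""
    return _fit_mixed("S2" if group_interaction else "S1", table)


def common_rows(table: pd.DataFrame, specs: list[str]) -> pd.DataFrame:
    """Restrict the table to rows complete for *every* listed model, so their
    BICs are comparable."""
    cols = sorted({c for s in specs for c in MODEL_SPECS[s][1]})
    return table.dropna(subset=cols)


def compare_bic(a: MixedFitResult, b: MixedFitResult) -> float:
    """Delta BIC = BIC(b) - BIC(a); negative favours b.  Requires both models
    fitted on identical rows."""
    if a.n_rows != b.n_rows:
        raise ValueError(
            f"BIC not comparable: {a.name} fitted on {a.n_rows} rows, "
            f"{b.name} on {b.n_rows}")
    return float(b.bic - a.bic)


def results_to_csv(results: list[MixedFitResult], path) -> None:
    """One row per fixed effect across all fitted models."""
    frames = []
    for r in results:
        df = r.fixed_effects.reset_index(names="term")
        df.insert(0, "model", r.name)
        df["bic"] = r.bic
        df["n_rows"] = r.n_rows
        df["singular"] = r.singular
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def results_report(results: list[MixedFitResult]) -> str:
    """Human-readable text report."""
    lines = []
    for r in results:
        lines.append(f"== {r.name}: {r.formula} + (1|subject)")
        lines.append(f"   n = {r.n_rows} rows, {r.n_subjects} subjects; "
                     f"BIC = {r.bic:.1f}; random-intercept var = {r.re_var:.4f}; "
                     f"residual var = {r.resid_var:.4f}"
                     + ("  [singular]" if r.singular else ""))
        for term, row in r.fixed_effects.iterrows():
            lines.append(f"   {term:<28s} {row['estimate']:+.4f} "
                         f"(se {row['se']:.4f})  t({int(row['df'])}) = "
                         f"{row['t']:+.2f}, p = {row['p']:.3g}")
        lines.append("")
    return "\n".join(lines)
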