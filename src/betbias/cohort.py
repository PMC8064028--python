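"""Synthetic participants for the reversal betting task.

Each simulated agent learns option values with a Rescorla-Wagner delta rule,
chooses by a softmax over the value difference, places an ordinal bet (1-5)
through a linear policy over within-session z-scaled internal signals, and
rates its surprise at the outcome.  Group phenotypes (healthy controls,
unilateral medial-prefrontal lesions, a bilateral-lesion case) differ only in
the distribution of ``AgentParams``; the simulation code path is identical.

Bet policy (continuous latent, before optional discretization)::

    bet_t = b0 + w_chosen * z(Q_chosen) + w_unchosen * z(Q_unchosen)
               + w_prev_bet * z(bet_{t-1}) + w_winstay * prev_win * stay
               + Normal(0, bet_noise_sd)

where z(.) is a within-session z-score, ``prev_win`` and ``stay`` are +/-1
indicators (the interaction term is 0 on block-initial trials, where the
previous trial is undefined).  Because z(bet_{t-1}) depends on the moments of
the bets themselves, the session is generated by a short fixed-point
iteration on those two scalars; at convergence the generated bets are an
exact linear function of the same z-scaled predictors the analysis stage
constructs, so coefficient-recovery tests are direct.

Surprise policy (1 = "I knew it!", 5 = "very surprised")::

    surprise_t = s0 + s_reward * z(R_t) + s_reward_x_value * z(R_t) * z(Q_chosen)
                    + Normal(0, surprise_noise_sd)

with the win indicator R z-scored within session.  Surprise is missing
before the onset trial (trial 10, 1-based), matching the task procedure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TaskConfig, TaskSchedule, generate_schedule

__all__ = [
    "AgentParams",
    "CohortSpec",
    "SESSION_COLUMNS",
    "simulate_agent",
    "simulate_cohort",
    "total_winnings",
    "control_spec",
    "unilateral_spec",
    "bilateral_spec",
    "additive_spec",
    "recovery_spec",
    "session_to_csv",
    "session_from_csv",
    "write_cohort",
    "read_cohort",
    "sessions_frame",
]

#: Column order of a session log (one row per trial).  ``q_*_gen`` and
#: ``p_win_*`` record generative provenance only and never exist for real data.
SESSION_COLUMNS = [
    "subject_id", "group_label", "block", "trial", "choice", "stay",
    "bet_level", "bet_money", "reward", "surprise",
    "p_win_chosen", "p_win_unchosen", "q_chosen_gen", "q_unchosen_gen",
]


@dataclass
class AgentParams:
    """Generative parameters of one synthetic participant.

    Learning/choice: ``alpha`` (learning rate), ``beta`` (inverse
    temperature), ``q0`` (initial value, midpoint of the 0/1 reward scale).
    Bet policy weights are in bet-scale units per z-unit of their predictor.
    Surprise weights likewise on the 1-5 surprise scale.
    """

    alpha: float = 0.3
    beta: float = 5.0
    q0: float = 0.5
    bet_intercept: float = 2.63
    w_chosen: float = 0.312
    w_prev_bet: float = 0.35
    w_unchosen: float = -0.089
    w_winstay: float = 0.10
    bet_noise_sd: float = 0.8
    s_intercept: float = 3.0
    s_reward: float = -0.45
    s_reward_x_value: float = -0.15
    surprise_noise_sd: float = 0.8

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        if not (0.0 <= self.q0 <= 1.0):
            raise ValueError(f"q0={self.q0} outside [0, 1]")
        if self.bet_noise_sd < 0 or self.surprise_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class CohortSpec:
    """Distributional description of one simulated group.

    Subject-level parameters are drawn independently as
    ``Normal(mean, sd)`` per ``AgentParams`` field (sd from ``param_sds``,
    default 0) and clipped into the parameter's valid range.  ``p_incomplete``
    subjects stop early at a Normal(completion_mean, completion_sd) fraction
    of the session, emulating real cohorts where not everyone finished.
    """

    group_label: str = "control"
    n_subjects: int = 33
    param_means: AgentParams = field(default_factory=AgentParams)
    param_sds: dict[str, float] = field(default_factory=dict)
    bet_mode: str = "discrete"  # "discrete" | "continuous"
    seed: int = 0
    p_incomplete: float = 0.0
    completion_mean: float = 0.90
    completion_sd: float = 0.06
    min_completion: float = 0.30

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(v < 0 for v in self.param_sds.values()):
            raise ValueError("parameter sds must be >= 0")
        if self.bet_mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown bet_mode {self.bet_mode!r}")
        unknown = set(self.param_sds) - {f.name for f in dataclasses.fields(AgentParams)}
        if unknown:
            raise ValueError(f"param_sds keys not AgentParams fields: {sorted(unknown)}")


def _zscore(x: np.ndarray) -> np.ndarray:
    """Population (ddof=0) z-score; all-constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _discretize(latent: np.ndarray, n_levels: int = 5) -> np.ndarray:
    return np.clip(np.rint(latent), 1, n_levels)


def simulate_agent(params: AgentParams, schedule: TaskSchedule, config: TaskConfig,
                   rng: np.random.Generator, *, n_trials: int | None = None,
                   subject_id: str = "agent", group_label: str = "control",
                   bet_mode: str = "discrete") -> pd.DataFrame:
    """Simulate one session; returns a trial-by-trial log (``SESSION_COLUMNS``).

    In continuous bet mode ``bet_level`` is the unrounded latent bet (kept
    unclipped so the linear generative structure is exact); ``bet_money``
    always maps through the nearest ordinal level.
    """
    params.validate()
    n = int(n_trials) if n_trials is not None else config.n_trials
    if not (1 <= n <= schedule.n_trials):
        raise ValueError("n_trials must be in [1, schedule length]")
    block = config.block_of_trial()[:n]

    choice = np.empty(n, dtype=int)
    reward = np.empty(n, dtype=int)
    qc = np.empty(n)
    qu = np.empty(n)
    p_chosen = np.empty(n)
    p_unchosen = np.empty(n)
    stay = np.full(n, np.nan)

    q = [params.q0, params.q0]
    beta = params.beta
    alpha = params.alpha
    u = rng.random(n)       # choice draws
    v = rng.random(n)       # outcome draws
    prev_choice = -1
    for t in range(n):
        # softmax over the value difference: P(choose 1) = logistic(beta*(q1-q0))
        p1 = 1.0 / (1.0 + np.exp(-beta * (q[1] - q[0])))
        c = int(u[t] < p1)
        r = int(v[t] < schedule.p_win[t, c])
        choice[t] = c
        reward[t] = r
        qc[t] = q[c]
        qu[t] = q[1 - c]
        p_chosen[t] = schedule.p_win[t, c]
        p_unchosen[t] = schedule.p_win[t, 1 - c]
        if t > 0 and block[t] == block[t - 1]:
            stay[t] = 1.0 if c == prev_choice else -1.0
        q[c] = q[c] + alpha * (r - q[c])
        prev_choice = c

    zqc = _zscore(qc)
    zqu = _zscore(qu)
    prev_win_pm = np.zeros(n)
    prev_win_pm[1:] = 2.0 * reward[:-1] - 1.0
    winstay = np.where(np.isnan(stay), 0.0, prev_win_pm * np.nan_to_num(stay))

    noise = rng.normal(0.0, params.bet_noise_sd, n) if params.bet_noise_sd > 0 else np.zeros(n)
    base = (params.bet_intercept + params.w_chosen * zqc
            + params.w_unchosen * zqu + params.w_winstay * winstay + noise)
    prev_defined = ~np.isnan(stay)
    if params.w_prev_bet == 0.0 or not prev_defined.any():
        bets = base
    else:
        # Fixed point on (mean, sd) of the previous-bet column so that the
        # generator's z-scaling matches the analysis-side convention exactly.
        m, s = params.bet_intercept, 1.0
        idx_prev = np.flatnonzero(prev_defined)
        bets = np.array(base)
        for _ in range(200):
            b = np.empty(n)
            for t in range(n):
                if prev_defined[t]:
                    b[t] = base[t] + params.w_prev_bet * (b[t - 1] - m) / s
                else:
                    b[t] = base[t]
            pv = b[idx_prev - 1]
            m2, s2 = float(pv.mean()), max(float(pv.std()), 1e-8)
            bets = b
            if abs(m2 - m) < 1e-13 and abs(s2 - s) < 1e-13:
                break
            m, s = m2, s2

    if bet_mode == "discrete":
        bet_level = _discretize(bets, config.n_bet_levels)
    elif bet_mode == "continuous":
        bet_level = bets
    else:
        raise ValueError(f"unknown bet_mode {bet_mode!r}")
    money_idx = _discretize(bets, config.n_bet_levels).astype(int) - 1
    bet_money = np.asarray(config.bet_money_values, dtype=float)[money_idx]

    zr = _zscore(reward.astype(float))
    s_noise = (rng.normal(0.0, params.surprise_noise_sd, n)
               if params.surprise_noise_sd > 0 else np.zeros(n))
    s_latent = (params.s_intercept + params.s_reward * zr
                + params.s_reward_x_value * zr * zqc + s_noise)
    surprise = _discretize(s_latent) if bet_mode == "discrete" else s_latent
    surprise = surprise.astype(float)
    surprise[: config.surprise_onset_trial - 1] = np.nan  # trials 1..onset-1 unrated

    return pd.DataFrame({
        "subject_id": subject_id,
        "group_label": group_label,
        "block": block,
        "trial": np.arange(1, n + 1),
        "choice": choice,
        "stay": stay,
        "bet_level": bet_level,
        "bet_money": bet_money,
        "reward": reward,
        "surprise": surprise,
        "p_win_chosen": p_chosen,
        "p_win_unchosen": p_unchosen,
        "q_chosen_gen": qc,
        "q_unchosen_gen": qu,
    }, columns=SESSION_COLUMNS)


_CLIP = {
    "alpha": (0.0, 1.0),
    "q0": (0.0, 1.0),
    "beta": (0.0, np.inf),
    "bet_noise_sd": (0.0, np.inf),
    "surprise_noise_sd": (0.0, np.inf),
}


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> AgentParams:
    kwargs = {}
    for f in dataclasses.fields(AgentParams):
        mean = getattr(spec.param_means, f.name)
        sd = spec.param_sds.get(f.name, 0.0)
        val = mean + sd * rng.standard_normal() if sd > 0 else float(mean)
        lo, hi = _CLIP.get(f.name, (-np.inf, np.inf))
        kwargs[f.name] = float(np.clip(val, lo, hi))
    return AgentParams(**kwargs)


def simulate_cohort(spec: CohortSpec, config: TaskConfig | None = None,
                    ) -> list[pd.DataFrame]:
    """Simulate ``spec.n_subjects`` sessions, each with an independent
    schedule seed and subject-level parameters; deterministic given
    ``spec.seed``."""
    spec.validate()
    if config is None:
        config = TaskConfig()
    sessions = []
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sched_seed = int(rng.integers(2 ** 31))
        schedule = generate_schedule(config, seed=sched_seed)
        params = _draw_params(spec, rng)
        n = config.n_trials
        if spec.p_incomplete > 0 and rng.random() < spec.p_incomplete:
            frac = float(np.clip(rng.normal(spec.completion_mean, spec.completion_sd),
                                 spec.min_completion, 1.0))
            n = max(1, int(round(frac * config.n_trials)))
        s = simulate_agent(
            params, schedule, config, rng, n_trials=n,
            subject_id=f"{spec.group_label}_{i:03d}",
            group_label=spec.group_label, bet_mode=spec.bet_mode)
        s.attrs["params"] = dataclasses.asdict(params)
        s.attrs["schedule_seed"] = sched_seed
        sessions.append(s)
    return sessions


def total_winnings(session: pd.DataFrame) -> float:
    """Sum over trials of the stake, signed by win/loss."""
    if len(session) == 0:
        raise ValueError("empty session")
    sign = 2.0 * session["reward"].to_numpy(dtype=float) - 1.0
    return float(np.sum(sign * session["bet_money"].to_numpy(dtype=float)))


# ---------------------------------------------------------------------------
# Group presets.  Control bet/surprise policy weights are the published
# fixed-effect scales for healthy participants (chosen value +0.312,
# unchosen value -0.089 bet units per z-unit; mean bet level 2.63 +/- 0.87);
# lesion phenotypes alter only the documented biases: unilateral cases bet
# more overall (3.55 +/- 0.70), lose the unchosen-value bias (~+0.001) and
# have a weakened previous-bet bias; the bilateral phenotype bets high
# (3.76), has elevated value sensitivity (+0.53 above controls) and a
# near-zero previous-bet bias.  Where only a t statistic was published
# (previous-bet and win-stay effects), magnitudes are package choices
# documented in the methods note.
# ---------------------------------------------------------------------------

_CONTROL_SDS = {
    "alpha": 0.10, "beta": 1.5, "bet_intercept": 0.87,
    "w_chosen": 0.08, "w_prev_bet": 0.08, "w_unchosen": 0.04,
    "w_winstay": 0.05, "s_reward": 0.10, "s_reward_x_value": 0.05,
}


def control_spec(n_subjects: int = 33, seed: int = 0,
                 bet_mode: str = "discrete") -> CohortSpec:
    """Healthy-control phenotype."""
    return CohortSpec(
        group_label="control", n_subjects=n_subjects, seed=seed,
        param_means=AgentParams(), param_sds=dict(_CONTROL_SDS),
        bet_mode=bet_mode, p_incomplete=7 / 33,
        completion_mean=0.90, completion_sd=0.06)


def unilateral_spec(n_subjects: int = 16, seed: int = 0,
                    bet_mode: str = "discrete") -> CohortSpec:
    """Unilateral medial-prefrontal lesion phenotype: higher bets, weakened
    previous-bet bias, absent unchosen-value bias, larger win/loss surprise
    asymmetry."""
    sds = dict(_CONTROL_SDS)
    sds["bet_intercept"] = 0.70
    means = AgentParams(bet_intercept=3.55, w_prev_bet=0.15, w_unchosen=0.001,
                        s_reward=-0.90)
    return CohortSpec(
        group_label="unilateral", n_subjects=n_subjects, seed=seed,
        param_means=means, param_sds=sds, bet_mode=bet_mode,
        p_incomplete=9 / 16, completion_mean=0.74, completion_sd=0.12)


def bilateral_spec(n_subjects: int = 1, seed: int = 0,
                   bet_mode: str = "discrete") -> CohortSpec:
    """Bilateral vmPFC-lesion phenotype: strategic betting — elevated
    chosen-value sensitivity, near-zero previous-bet bias, strong win-stay
    interaction, high overall bets, and low bet noise (bets reliably follow
    value, as in the published winnings-by-bet profile)."""
    means = AgentParams(bet_intercept=3.76, w_chosen=0.842, w_prev_bet=0.05,
                        w_unchosen=-0.089, w_winstay=0.40, bet_noise_sd=0.5)
    return CohortSpec(group_label="bilateral", n_subjects=n_subjects, seed=seed,
                      param_means=means, param_sds={}, bet_mode=bet_mode)


def additive_spec(n_subjects: int = 40, seed: int = 0,
                  bet_mode: str = "discrete") -> CohortSpec:
    """Null bet policy for calibration checks: bets are intercept plus noise
    only.  With any value sensitivity (w_chosen > 0) a genuine win-stay
    interaction in cell-mean bets is *induced* through the learned value
    (after a win, staying means betting on a just-reinforced option), so
    type-I-error checks of the 2x2 ANOVA need this pathway switched off."""
    means = AgentParams(w_chosen=0.0, w_unchosen=0.0, w_prev_bet=0.0,
                        w_winstay=0.0)
    return CohortSpec(group_label="control", n_subjects=n_subjects, seed=seed,
                      param_means=means,
                      param_sds={"alpha": 0.10, "beta": 1.5, "bet_intercept": 0.5},
                      bet_mode=bet_mode)


def recovery_spec(n_subjects: int = 40, seed: int = 0, *,
                  w_chosen: float = 0.312, w_unchosen: float = -0.089,
                  w_prev_bet: float = 0.0, w_winstay: float = 0.0,
                  bet_noise_sd: float = 0.8) -> CohortSpec:
    """Coefficient-recovery cohort: continuous bets, complete sessions, the
    published healthy value coefficients as generating fixed effects, and no
    trial-history effects unless requested."""
    means = AgentParams(w_chosen=w_chosen, w_unchosen=w_unchosen,
                        w_prev_bet=w_prev_bet, w_winstay=w_winstay,
                        bet_noise_sd=bet_noise_sd)
    sds = {"alpha": 0.10, "beta": 1.5, "bet_intercept": 0.50}
    return CohortSpec(group_label="control", n_subjects=n_subjects, seed=seed,
                      param_means=means, param_sds=sds, bet_mode="continuous")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def session_to_csv(session: pd.DataFrame, path) -> None:
    session.to_csv(path, index=False)


def session_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns
               and not c.endswith("_gen") and not c.startswith("p_win")]
    if missing:
        raise ValueError(f"session file {path} missing columns: {missing}")
    return df


def write_cohort(sessions: list[pd.DataFrame], out_dir) -> Path:
    """One CSV per subject plus a cohort manifest (subject, group, n_trials)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        sid = s["subject_id"].iloc[0]
        session_to_csv(s, out / f"{sid}.csv")
        row = {"subject_id": sid, "group_label": s["group_label"].iloc[0],
               "n_trials": len(s),
               "schedule_seed": s.attrs.get("schedule_seed", "")}
        row.update(s.attrs.get("params", {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "cohort_manifest.csv", index=False)
    return out


def read_cohort(in_dir) -> list[pd.DataFrame]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "cohort_manifest.csv")
    return [session_from_csv(in_dir / f"{sid}.csv")
            for sid in manifest["subject_id"]]


def sessions_frame(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate session logs into one long trial table."""
    return pd.concat(sessions, ignore_index=True)
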