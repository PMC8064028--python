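"""Rescorla-Wagner + softmax model: likelihood, ML fitting, value traces.

Learning rule (chosen option only; the unchosen value is frozen)::

    Q_chosen <- Q_chosen + alpha * (R - Q_chosen),  R in {0, 1}

Choice rule: logistic (softmax over two options) on the value difference,
``P(choice) = logistic(beta * (Q_chosen - Q_unchosen))``.  Two free
parameters: learning rate ``alpha`` and inverse temperature ``beta``.

Fitting is deterministic multi-start maximum likelihood on transformed
parameters (logit alpha, log beta) with L-BFGS-B, seeded Latin-hypercube
starts.  Values are updated by the win/loss indicator irrespective of the
amount bet.  The reconstructed value traces are *pre-outcome*: ``trace[t]``
is the value the trial-t choice and bet were conditioned on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import qmc

__all__ = [
    "ALPHA_BOUNDS", "BETA_BOUNDS", "RWFit",
    "rw_loglik", "fit_rw", "reconstruct_values",
    "fits_to_csv", "traces_to_csv",
]

ALPHA_BOUNDS = (0.001, 0.999)
BETA_BOUNDS = (0.01, 50.0)
MIN_TRIALS = 20
Q0_DEFAULT = 0.5


@dataclass
class RWFit:
    """Per-subject maximum-likelihood fit of the learning/choice model."""

    alpha_hat: float
    beta_hat: float
    loglik: float
    n_fitted_trials: int
    predictive_accuracy: float
    q_chosen: np.ndarray
    q_unchosen: np.ndarray


def _extract(session) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(session, pd.DataFrame):
        return (session["choice"].to_numpy(dtype=int),
                session["reward"].to_numpy(dtype=int))
    choices, rewards = session
    return np.asarray(choices, dtype=int), np.asarray(rewards, dtype=int)


def rw_loglik(alpha: float, beta: float, session, q0: float = Q0_DEFAULT) -> float:
    """Log-likelihood of the observed choices under (alpha, beta).

    ``session`` is a session DataFrame or a ``(choices, rewards)`` pair of
    0/1 arrays.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if beta < 0:
        raise ValueError(f"beta={beta} must be >= 0")
    choices, rewards = _extract(session)
    if len(choices) == 0:
        raise ValueError("empty session")
    q = [q0, q0]
    ll = 0.0
    log1p, exp = math.log1p, math.exp
    for c, r in zip(choices.tolist(), rewards.tolist()):
        d = beta * (q[c] - q[1 - c])
        # log logistic(d), stable for large |d|
        ll += -log1p(exp(-d)) if d > -30 else d
        q[c] += alpha * (r - q[c])
    return ll


def reconstruct_values(alpha: float, session, q0: float = Q0_DEFAULT,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic replay of the learning rule; pre-outcome value traces."""
    choices, rewards = _extract(session)
    n = len(choices)
    qc = np.empty(n)
    qu = np.empty(n)
    q = [q0, q0]
    for t, (c, r) in enumerate(zip(choices.tolist(), rewards.tolist())):
        qc[t] = q[c]
        qu[t] = q[1 - c]
        q[c] += alpha * (r - q[c])
    return qc, qu


def _predictive_accuracy(qc: np.ndarray, qu: np.ndarray) -> float:
    """Proportion of trials where the model's higher-valued option matches the
    actual choice; exact value ties count one half."""
    hits = np.where(qc > qu, 1.0, np.where(qc < qu, 0.0, 0.5))
    return float(hits.mean())


def fit_rw(session, n_starts: int = 10, seed: int = 0,
           q0: float = Q0_DEFAULT) -> RWFit:
    """Multi-start ML fit; ``session`` may be one session or a list of
    sessions (independent value recursions, summed likelihood)."""
    sessions = session if isinstance(session, list) else [session]
    data = [_extract(s) for s in sessions]
    n_total = sum(len(c) for c, _ in data)
    if n_total < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials, got {n_total}")

    lo = np.array([logit(ALPHA_BOUNDS[0]), np.log(BETA_BOUNDS[0])])
    hi = np.array([logit(ALPHA_BOUNDS[1]), np.log(BETA_BOUNDS[1])])

    def negll(theta: np.ndarray) -> float:
        a = float(expit(theta[0]))
        b = float(np.exp(theta[1]))
        return -sum(rw_loglik(a, b, d, q0=q0) for d in data)

    sampler = qmc.LatinHypercube(d=2, rng=np.random.default_rng(seed))
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")

    alpha_hat = float(expit(best.x[0]))
    beta_hat = float(np.exp(best.x[1]))
    traces = [reconstruct_values(alpha_hat, d, q0=q0) for d in data]
    qc = np.concatenate([t[0] for t in traces])
    qu = np.concatenate([t[1] for t in traces])
    return RWFit(alpha_hat=alpha_hat, beta_hat=beta_hat,
                 loglik=-float(best.fun), n_fitted_trials=n_total,
                 predictive_accuracy=_predictive_accuracy(qc, qu),
                 q_chosen=qc, q_unchosen=qu)


def fits_to_csv(fits: dict[str, RWFit], path) -> None:
    """One row per subject: alpha_hat, beta_hat, loglik, accuracy, n_trials."""
    rows = [{"subject_id": sid, "alpha_hat": f.alpha_hat, "beta_hat": f.beta_hat,
             "loglik": f.loglik, "predictive_accuracy": f.predictive_accuracy,
             "n_trials": f.n_fitted_trials} for sid, f in fits.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def traces_to_csv(fits: dict[str, RWFit], path) -> None:
    """Per-trial value traces keyed by subject and 1-based trial."""
    frames = []
    for sid, f in fits.items():
        frames.append(pd.DataFrame({
            "subject_id": sid,
            "trial": np.arange(1, f.n_fitted_trials + 1),
            "q_chosen": f.q_chosen,
            "q_unchosen": f.q_unchosen,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
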