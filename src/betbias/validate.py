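"""Schema and invariant validation of session log files.

All violations are collected and returned, not just the first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["validate_session_file", "validate_session"]

_REQUIRED = ["subject_id", "group_label", "block", "trial", "choice", "stay",
             "bet_level", "bet_money", "reward", "surprise"]


def validate_session(df: pd.DataFrame, surprise_onset_trial: int = 10) -> list[str]:
    """Range and invariant checks on an in-memory session log; returns all
    violations as human-readable strings (empty list = valid)."""
    errs: list[str] = []
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        errs.append(f"missing columns: {missing}")
        return errs
    if len(df) == 0:
        errs.append("empty session")
        return errs

    trial = df["trial"].to_numpy()
    if not np.all(np.diff(trial) > 0):
        errs.append("trial index not strictly increasing")
    block = df["block"].to_numpy()
    if not np.all(np.diff(block) >= 0):
        errs.append("block index not monotone")

    choice = df["choice"].to_numpy()
    bad = ~np.isin(choice, (0, 1))
    if bad.any():
        errs.append(f"{bad.sum()} choice values outside {{0,1}}")
    reward = df["reward"].to_numpy()
    bad = ~np.isin(reward, (0, 1))
    if bad.any():
        errs.append(f"{bad.sum()} reward values outside {{0,1}}")

    bet = df["bet_level"].to_numpy(dtype=float)
    bad = ~np.isfinite(bet) | (bet < 1) | (bet > 5)
    if bad.any():
        errs.append(f"{bad.sum()} bet_level values outside [1, 5]")

    stay = df["stay"].to_numpy(dtype=float)
    block_initial = np.r_[True, block[1:] != block[:-1]]
    if np.any(np.isfinite(stay[block_initial])):
        errs.append("stay defined on a block-initial trial")
    interior = ~block_initial
    bad = interior & ~np.isin(stay, (-1.0, 1.0))
    if bad.any():
        errs.append(f"{bad.sum()} interior stay values not in {{-1,+1}}")

    surprise = df["surprise"].to_numpy(dtype=float)
    pre = trial < surprise_onset_trial
    if np.any(np.isfinite(surprise[pre])):
        errs.append(f"surprise present before onset trial {surprise_onset_trial}")
    rated = np.isfinite(surprise)
    bad = rated & ((surprise < 1) | (surprise > 5))
    if bad.any():
        errs.append(f"{bad.sum()} surprise values outside [1, 5]")
    return errs


def validate_session_file(path, surprise_onset_trial: int = 10) -> list[str]:
    """Validate a session CSV; unreadable files raise, schema/range
    violations are returned."""
    df = pd.read_csv(path)
    return validate_session(df, surprise_onset_trial=surprise_onset_trial)
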