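"""Reversal-learning task design: schedules, outcome sampling, diagnostics.

The task is a two-armed bandit with post-decision wagering.  Each of the two
options (0 and 1) independently pays off with probability ``p_low`` or
``p_high`` (0.3 / 0.7 by default).  The pair of probabilities is piecewise
constant, reversing jointly every 8 or 16 trials, with the inter-reversal
intervals drawn in equal numbers of 8s and 16s so their mean is exactly 12.
Over an initial balance window (128 trials by default) each of the four joint
probability combinations occupies exactly a quarter of the trials.

Construction is a seeded randomized backtracking search; failure to satisfy
the constraints within the attempt budget is an error, never a silent
relaxation.  Trial indices are 0-based half-open internally and 1-based in
every exported file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "TaskSchedule",
    "ScheduleConstructionError",
    "generate_schedule",
    "sample_outcome",
    "sample_outcomes",
    "schedule_diagnostics",
    "schedule_to_csv",
    "schedule_from_csv",
    "config_to_file",
    "config_from_file",
]

# Joint probability state -> (option0 high?, option1 high?)
_STATES = ((False, False), (False, True), (True, False), (True, True))


class ScheduleConstructionError(RuntimeError):
    """Raised when no schedule satisfying the design constraints is found."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the reversal betting task.

    Defaults reproduce the published design: 160 trials in 3 blocks, win
    probabilities in {0.3, 0.7}, reversals every 8 or 16 trials, stakes of
    £1/£2/£5/£10/£20 on an ordinal 1-5 bet scale, surprise ratings collected
    from trial 10 (1-based) onwards.
    """

    n_trials: int = 160
    n_blocks: int = 3
    p_high: float = 0.7
    p_low: float = 0.3
    interval_lengths: tuple[int, ...] = (8, 16)
    balance_window: int = 128
    bet_money_values: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)
    surprise_onset_trial: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low < self.p_high < 1.0):
            raise ValueError("require 0 < p_low < p_high < 1")
        if self.n_trials < 1 or self.n_blocks < 1:
            raise ValueError("n_trials and n_blocks must be positive")
        if any(b <= 0 for b in self.interval_lengths) or not self.interval_lengths:
            raise ValueError("all interval lengths must be positive")
        if not (0 < self.balance_window <= self.n_trials):
            raise ValueError("balance_window must be in (0, n_trials]")
        bm = self.bet_money_values
        if len(bm) != 5:
            raise ValueError("bet_money_values must have length 5")
        if any(lo >= hi for lo, hi in zip(bm[:-1], bm[1:])):
            raise ValueError("bet_money_values must be strictly increasing")
        if not (1 <= self.surprise_onset_trial <= self.n_trials):
            raise ValueError("surprise_onset_trial out of range")

    @property
    def n_bet_levels(self) -> int:
        return len(self.bet_money_values)

    def block_of_trial(self) -> np.ndarray:
        """1-based block index for each 0-based trial, blocks as even as possible."""
        parts = np.array_split(np.arange(self.n_trials), self.n_blocks)
        out = np.empty(self.n_trials, dtype=int)
        for b, idx in enumerate(parts, start=1):
            out[idx] = b
        return out


@dataclass
class TaskSchedule:
    """Per-trial win probabilities for both options plus reversal bookkeeping.

    ``designed_intervals`` records the inter-reversal intervals as drawn,
    before truncation at ``n_trials``, so the exact mean-12 property remains
    testable.  ``None`` for schedules imported from CSV (draws unrecoverable).
    """

    p_win: np.ndarray  # shape (n_trials, 2)
    reversal_trials: list[int]
    designed_intervals: list[int] | None
    p_low: float = 0.3
    p_high: float = 0.7

    @property
    def n_trials(self) -> int:
        return int(self.p_win.shape[0])

    def states(self) -> np.ndarray:
        """Joint state index (0-3) per trial: 2*(option0 high) + (option1 high)."""
        hi = self.p_win > (self.p_low + self.p_high) / 2.0
        return (2 * hi[:, 0] + hi[:, 1]).astype(int)


def _state_probs(state: int, p_low: float, p_high: float) -> tuple[float, float]:
    a_hi, b_hi = _STATES[state][0], _STATES[state][1]
    # _STATES index == 2*a_hi + b_hi by construction of the tuple order
    return (p_high if a_hi else p_low, p_high if b_hi else p_low)


def _assign_states(contrib: np.ndarray, need_each: int, rng: np.random.Generator,
                   node_budget: int = 20000) -> list[int] | None:
    """Backtracking assignment of joint states to interval segments.

    Satisfies the balance-window occupancy exactly; among feasible branches
    prefers the least-used (previous state -> next state) transition so
    transition-type coverage is maximized greedily.  Consecutive states must
    differ (every boundary is a genuine reversal).
    """
    n_seg = len(contrib)
    trans_count = [[0] * 4 for _ in range(4)]
    need = [need_each] * 4
    path: list[int] = []
    nodes = 0

    def rec(i: int, prev: int | None) -> bool:
        nonlocal nodes
        if i == n_seg:
            return True
        nodes += 1
        if nodes > node_budget:
            return False
        c = int(contrib[i])
        cands = [s for s in range(4)
                 if (prev is None or s != prev) and need[s] >= c]
        rng.shuffle(cands)
        if prev is not None:
            cands.sort(key=lambda s: trans_count[prev][s])
        for s in cands:
            path.append(s)
            need[s] -= c
            if prev is not None:
                trans_count[prev][s] += 1
            if rec(i + 1, s):
                return True
            path.pop()
            need[s] += c
            if prev is not None:
                trans_count[prev][s] -= 1
        return False

    return path if rec(0, None) else None


def generate_schedule(config: TaskConfig, seed: int | None = None,
                      max_attempts: int = 2000) -> TaskSchedule:
    """Generate a balanced reversal schedule.

    Priorities, in order: (1) intervals drawn from ``interval_lengths`` in
    equal numbers (mean exactly the midpoint, 12 by default); (2) exact
    equal occupancy of the four probability combinations over the balance
    window; (3) greedy coverage of transition types.  Deterministic given
    ``seed`` (defaults to ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    w = config.balance_window
    if w % 4 != 0:
        raise ScheduleConstructionError(
            f"balance_window={w} not divisible by 4; equal occupancy unsatisfiable")
    lengths = np.asarray(sorted(config.interval_lengths), dtype=int)
    per_len = math.ceil(config.n_trials / int(lengths.sum()))
    base = np.repeat(lengths, per_len)

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        intervals = rng.permutation(base)
        bounds = np.cumsum(intervals)
        starts = np.concatenate(([0], bounds[:-1]))
        contrib = np.clip(np.minimum(bounds, w) - np.minimum(starts, w), 0, None)
        states = _assign_states(contrib, w // 4, rng)
        if states is None:
            continue
        p_win = np.empty((config.n_trials, 2))
        reversal_trials: list[int] = []
        prev_state: int | None = None
        for st, s0, s1 in zip(states, starts, bounds):
            if s0 >= config.n_trials:
                break
            pa, pb = _state_probs(st, config.p_low, config.p_high)
            p_win[s0:min(int(s1), config.n_trials)] = (pa, pb)
            if prev_state is not None and st != prev_state:
                reversal_trials.append(int(s0))
            prev_state = st
        return TaskSchedule(
            p_win=p_win,
            reversal_trials=reversal_trials,
            designed_intervals=[int(x) for x in intervals],
            p_low=config.p_low,
            p_high=config.p_high,
        )
    raise ScheduleConstructionError(
        f"no balanced schedule found in {max_attempts} attempts")


def sample_outcome(p_win_chosen: float, rng: np.random.Generator) -> int:
    """Draw a 0/1 win indicator with the chosen option's current probability."""
    if not (0.0 <= p_win_chosen <= 1.0):
        raise ValueError(f"win probability {p_win_chosen} outside [0, 1]")
    return int(rng.random() < p_win_chosen)


def sample_outcomes(p_win: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized win indicators, one per entry of ``p_win``."""
    p = np.asarray(p_win, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("win probabilities outside [0, 1]")
    return (rng.random(p.shape) < p).astype(int)


def schedule_diagnostics(schedule: TaskSchedule) -> dict:
    """Occupancy, transition-type and interval summaries for a schedule."""
    states = schedule.states()
    n = schedule.n_trials
    occupancy = {s: int(np.sum(states == s)) for s in range(4)}
    w = min(128, n)
    occupancy_window = {s: int(np.sum(states[:w] == s)) for s in range(4)}
    transitions: dict[tuple[int, int], int] = {}
    for t in schedule.reversal_trials:
        key = (int(states[t - 1]), int(states[t]))
        transitions[key] = transitions.get(key, 0) + 1
    edges = [0] + list(schedule.reversal_trials) + [n]
    observed = np.diff(edges)
    return {
        "n_trials": n,
        "occupancy": occupancy,
        "occupancy_window": occupancy_window,
        "window": w,
        "transition_counts": transitions,
        "n_reversals": len(schedule.reversal_trials),
        "interval_mean": float(np.mean(observed)),
        "interval_min": int(np.min(observed)),
        "interval_max": int(np.max(observed)),
    }


def schedule_to_csv(schedule: TaskSchedule, path) -> None:
    """Write schedule as CSV: trial (1-based), p_win_A, p_win_B, is_reversal."""
    n = schedule.n_trials
    is_rev = np.zeros(n, dtype=int)
    is_rev[np.asarray(schedule.reversal_trials, dtype=int)] = 1
    pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "p_win_A": schedule.p_win[:, 0],
        "p_win_B": schedule.p_win[:, 1],
        "is_reversal": is_rev,
    }).to_csv(path, index=False)


def schedule_from_csv(path) -> TaskSchedule:
    df = pd.read_csv(path)
    p_win = df[["p_win_A", "p_win_B"]].to_numpy(dtype=float)
    reversal_trials = (df.index[df["is_reversal"] == 1]).tolist()
    levels = np.unique(p_win)
    p_low = float(levels.min())
    p_high = float(levels.max())
    return TaskSchedule(p_win=p_win, reversal_trials=[int(t) for t in reversal_trials],
                        designed_intervals=None, p_low=p_low, p_high=p_high)


def config_to_file(config: TaskConfig, path) -> None:
    """Flat key-value (YAML) dump mirroring TaskConfig field names."""
    d = asdict(config)
    d["interval_lengths"] = list(d["interval_lengths"])
    d["bet_money_values"] = list(d["bet_money_values"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_file(path) -> TaskConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["interval_lengths"] = tuple(d["interval_lengths"])
    d["bet_money_values"] = tuple(d["bet_money_values"])
    return TaskConfig(**d)
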