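import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from betbias import TaskConfig, generate_schedule, simulate_cohort, control_spec

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="statsmodels.*")


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def schedule(config):
    return generate_schedule(config, seed=123)


@pytest.fixture(scope="session")
def control_sessions(config):
    """Small healthy-control cohort reused by read-only tests."""
    return simulate_cohort(control_spec(12, seed=42), config)


def make_session(choices, rewards, bets=None, blocks=None, surprise=None,
                 subject_id="toy", group_label="control",
                 money=(1.0, 2.0, 5.0, 10.0, 20.0)) -> pd.DataFrame:
    """Hand-built session log for toy examples."""
    n = len(choices)
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=int)
    bets = np.asarray(bets if bets is not None else np.full(n, 3), dtype=float)
    blocks = np.asarray(blocks if blocks is not None else np.ones(n, dtype=int))
    stay = np.full(n, np.nan)
    for t in range(1, n):
        if blocks[t] == blocks[t - 1]:
            stay[t] = 1.0 if choices[t] == choices[t - 1] else -1.0
    lev = np.clip(np.rint(bets), 1, 5).astype(int)
    return pd.DataFrame({
        "subject_id": subject_id,
        "group_label": group_label,
        "block": blocks,
        "trial": np.arange(1, n + 1),
        "choice": choices,
        "stay": stay,
        "bet_level": bets,
        "bet_money": np.asarray(money, dtype=float)[lev - 1],
        "reward": rewards,
        "surprise": (np.asarray(surprise, dtype=float) if surprise is not None
                     else np.full(n, np.nan)),
        "p_win_chosen": np.nan,
        "p_win_unchosen": np.nan,
        "q_chosen_gen": np.nan,
        "q_unchosen_gen": np.nan,
    })
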