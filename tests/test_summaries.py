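"""Win-stay summaries, 2x2 ANOVA, single-case tests and binned curves."""

import numpy as np
import pandas as pd
import pytest

from betbias.cohort import (AgentParams, CohortSpec, simulate_cohort,
                            control_spec, additive_spec)
from betbias.regression import prepare_predictors
from betbias.summaries import (arcsine_transform, winstay_summary,
                               cohort_winstay_table, bet_anova_2x2,
                               single_case_z, winnings_by_bet_bin,
                               quantile_sliding_curve,
                               residualized_prev_bet_curve)
from conftest import make_session


def _interaction_p(aov: pd.DataFrame) -> float:
    return float(aov.loc[aov["effect"].str.contains(r"\*"), "p"].iloc[0])


def test_arcsine_transform_properties():
    p = np.linspace(0, 1, 11)
    t = arcsine_transform(p)
    assert t[0] == 0.0
    assert t[-1] == pytest.approx(np.pi / 2)
    assert np.all(np.diff(t) > 0)
    with pytest.raises(ValueError):
        arcsine_transform(1.2)


def test_winstay_always_stay():
    s = make_session([0] * 12, [1, 0] * 6)
    row = winstay_summary(s)
    assert row["p_stay_after_win"] == 1.0
    assert row["p_stay_after_loss"] == 1.0
    assert row["arcsine_stay_after_win"] == pytest.approx(np.pi / 2)


def test_winstay_constant_bets_zero_interaction():
    rng = np.random.default_rng(0)
    s = make_session(rng.integers(0, 2, 60), rng.integers(0, 2, 60),
                     bets=[3] * 60)
    row = winstay_summary(s)
    if np.isfinite(row["interaction_term"]):
        assert row["interaction_term"] == 0.0


def test_winstay_hand_counted_toy():
    # trials:      1    2    3    4    5    6    7    8
    # choice:      A    A    B    B    B    A    A    A
    # reward:      1    0    0    1    1    1    0    0
    # bets:        2    4    1    3    5    2    4    2
    # conditioning (trials 2-8): prev outcome / stay
    #  t2: win/stay b4 ; t3: loss/switch b1 ; t4: loss/stay b3
    #  t5: win/stay b5 ; t6: win/switch b2  ; t7: win/stay b4
    #  t8: loss/stay b2
    s = make_session([0, 0, 1, 1, 1, 0, 0, 0], [1, 0, 0, 1, 1, 1, 0, 0],
                     bets=[2, 4, 1, 3, 5, 2, 4, 2])
    row = winstay_summary(s)
    assert row["p_stay_after_win"] == pytest.approx(3 / 4)
    assert row["p_stay_after_loss"] == pytest.approx(2 / 3)
    assert row["mean_bet_win_stay"] == pytest.approx((4 + 5 + 4) / 3)
    assert row["mean_bet_win_switch"] == pytest.approx(2.0)
    assert row["mean_bet_lose_stay"] == pytest.approx((3 + 2) / 2)
    assert row["mean_bet_lose_switch"] == pytest.approx(1.0)
    want = 0.5 * ((13 / 3 + 1.0) - (2.0 + 2.5))
    assert row["interaction_term"] == pytest.approx(want)


def test_winstay_empty_cell_is_missing():
    s = make_session([0] * 10, [1] * 10, bets=[3] * 10)  # never loses
    row = winstay_summary(s)
    assert np.isnan(row["p_stay_after_loss"])
    assert np.isnan(row["interaction_term"])


def test_anova_identical_cells_gives_zero_F():
    rows = []
    for i in range(6):
        rows.append({"subject_id": f"s{i}",
                     "mean_bet_win_stay": 3.0, "mean_bet_win_switch": 3.0,
                     "mean_bet_lose_stay": 3.0, "mean_bet_lose_switch": 3.0})
    aov = bet_anova_2x2(pd.DataFrame(rows))
    assert (aov["F"] == 0.0).all()
    assert (aov["p"] == 1.0).all()


def test_anova_invariant_to_per_subject_bet_offsets(config):
    tab = cohort_winstay_table(simulate_cohort(control_spec(12, seed=6), config))
    aov1 = bet_anova_2x2(tab)
    shifted = tab.copy()
    cols = [c for c in tab.columns if c.startswith("mean_bet_")]
    offsets = np.arange(len(shifted), dtype=float)
    for c in cols:
        shifted[c] = shifted[c] + offsets
    aov2 = bet_anova_2x2(shifted)
    assert np.allclose(aov1["F"], aov2["F"], rtol=1e-8, equal_nan=True)


def test_anova_detects_generated_winstay_interaction(config):
    """With a real win-stay bet policy the interaction is reliably found."""
    hits = 0
    for k in range(5):
        spec = control_spec(40, seed=800 + k)
        spec.param_means.w_winstay = 0.4
        tab = cohort_winstay_table(simulate_cohort(spec, config))
        hits += _interaction_p(bet_anova_2x2(tab)) < 0.05
    assert hits == 5


def test_single_case_z_examples():
    z, p = single_case_z(8.24, 8.24, 50.0)
    assert z == 0.0 and p == pytest.approx(1.0)
    # published comparison: patient winnings 114 vs controls 8.24 +/- 50.0
    z, _ = single_case_z(114, 8.24, 50.0)
    assert z == pytest.approx(2.11, abs=0.05)
    z, p = single_case_z(1.96, 0.0, 1.0)
    assert p == pytest.approx(0.05, abs=1e-3)
    # antisymmetric around the control mean
    zp, pp = single_case_z(10, 5, 2)
    zm, pm = single_case_z(0, 5, 2)
    assert zp == -zm and pp == pytest.approx(pm)
    with pytest.raises(ValueError):
        single_case_z(1, 0, 0)


def test_single_case_crawford_variant():
    t, p = single_case_z(114, 8.24, 50.0, method="crawford", n_controls=16)
    z, pz = single_case_z(114, 8.24, 50.0)
    assert abs(t) < abs(z)     # inflated sd
    assert p > pz              # heavier-tailed reference
    with pytest.raises(ValueError):
        single_case_z(1, 0, 1, method="crawford")


def test_winnings_by_bet_single_level():
    s = make_session([0] * 8, [1] * 8, bets=[3] * 8)  # level 3 pays 5
    curve = winnings_by_bet_bin(s)
    assert curve.loc[3] == pytest.approx(5.0)
    assert curve.drop(3).isna().all()


def test_winnings_by_bet_fair_coin_flat():
    rng = np.random.default_rng(2)
    n = 4000
    s = make_session(rng.integers(0, 2, n), rng.integers(0, 2, n),
                     bets=rng.integers(1, 6, n))
    curve = winnings_by_bet_bin(s)
    money = np.array([1, 2, 5, 10, 20], dtype=float)
    for lv in range(1, 6):
        se = money[lv - 1] / np.sqrt((np.rint(s['bet_level']) == lv).sum())
        assert abs(curve.loc[lv]) < 4 * se


def test_winnings_by_bet_strategic_agent_increasing():
    """An agent betting high only on high-probability trials earns more at
    high bet levels (by construction)."""
    rng = np.random.default_rng(3)
    n = 2000
    p = np.where(rng.random(n) < 0.5, 0.7, 0.3)
    bets = np.where(p == 0.7, 5, 1)
    rewards = (rng.random(n) < p).astype(int)
    s = make_session(np.zeros(n, dtype=int), rewards, bets=bets)
    curve = winnings_by_bet_bin(s)
    assert curve.loc[5] > 0 > curve.loc[1]


def test_quantile_curve_constant_response_flat():
    rng = np.random.default_rng(4)
    xs = {f"s{i}": rng.normal(size=100) for i in range(3)}
    ys = {k: np.full(100, 2.5) for k in xs}
    cur = quantile_sliding_curve(xs, ys)
    assert np.allclose(cur["y_mean"], 2.5)
    assert np.allclose(cur["y_sem"], 0.0)


def test_quantile_curve_monotone_map_increasing():
    rng = np.random.default_rng(5)
    xs = {f"s{i}": rng.normal(size=200) for i in range(4)}
    cur = quantile_sliding_curve(xs, {k: v for k, v in xs.items()})
    y = cur["y_mean"].to_numpy()
    assert np.all(np.diff(y) > 0)


def test_quantile_curve_matches_hand_binning():
    """Two subjects, coarse windows, checked against a literal re-binning."""
    x1 = np.arange(1.0, 41.0)          # ranks = values
    y1 = x1 ** 2
    x2 = np.linspace(0, 1, 50)
    y2 = 3.0 - x2
    cur = quantile_sliding_curve({"a": x1, "b": x2}, {"a": y1, "b": y2},
                                 width=50, step=25)
    for i, start in enumerate([0.0, 25.0, 50.0]):
        cells_x, cells_y = [], []
        for x, y in ((x1, y1), (x2, y2)):
            pct = (np.argsort(np.argsort(x)) + 1) / len(x) * 100.0
            m = (pct >= start) & (pct <= start + 50)
            cells_x.append(x[m].mean())
            cells_y.append(y[m].mean())
        assert cur.loc[i, "x"] == pytest.approx(np.mean(cells_x))
        assert cur.loc[i, "y_mean"] == pytest.approx(np.mean(cells_y))


def test_quantile_curve_drops_sparse_subjects():
    xs = {"rich": np.arange(100.0), "poor": np.arange(5.0)}
    ys = {"rich": np.arange(100.0), "poor": np.arange(5.0)}
    cur = quantile_sliding_curve(xs, ys)
    assert (cur["n_subjects"] <= 1).all()
    with pytest.raises(ValueError):
        quantile_sliding_curve({"poor": np.arange(5.0)},
                               {"poor": np.arange(5.0)})


def test_residual_curve_flat_without_prev_bet_effect(config):
    spec = CohortSpec(n_subjects=12, seed=20, bet_mode="continuous",
                      param_means=AgentParams(w_prev_bet=0.0, w_winstay=0.0),
                      param_sds={"alpha": 0.1})
    tab = prepare_predictors(simulate_cohort(spec, config))
    cur = residualized_prev_bet_curve(tab)
    slope = np.polyfit(cur["prev_bet_level"], cur["resid_mean"], 1)[0]
    assert abs(slope) < 0.1


def test_residual_curve_increasing_with_prev_bet_effect(config):
    spec = CohortSpec(n_subjects=12, seed=21, bet_mode="continuous",
                      param_means=AgentParams(w_prev_bet=0.5, w_winstay=0.0),
                      param_sds={"alpha": 0.1})
    tab = prepare_predictors(simulate_cohort(spec, config))
    cur = residualized_prev_bet_curve(tab)
    slope = np.polyfit(cur["prev_bet_level"], cur["resid_mean"], 1)[0]
    assert slope > 0.1


def test_residual_curve_steeper_for_stronger_bias(config):
    """The group with the larger previous-bet weight shows the steeper
    residual curve in most replicates (the lesion-contrast pattern)."""
    steeper = 0
    for k in range(8):
        slopes = {}
        for label, w in (("control", 0.45), ("lesion", 0.05)):
            spec = CohortSpec(n_subjects=10, seed=900 + k,
                              group_label=label, bet_mode="continuous",
                              param_means=AgentParams(w_prev_bet=w, w_winstay=0.0),
                              param_sds={"alpha": 0.1})
            tab = prepare_predictors(simulate_cohort(spec, config))
            cur = residualized_prev_bet_curve(tab)
            slopes[label] = np.polyfit(cur["prev_bet_level"],
                                       cur["resid_mean"], 1)[0]
        steeper += slopes["control"] > slopes["lesion"]
    assert steeper >= 7
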