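"""Survival machinery: stratification, Kaplan-Meier, log-rank, Cox."""

import math

import numpy as np
import pandas as pd
import pytest

from susceptigene import synthdata as sd
from susceptigene.survival import (
    SurvivalTable,
    cox_hr,
    hazard_screen,
    km_estimate,
    logrank_test,
    stratify_by_quantile,
)
from conftest import toy_survival
from oracles import km_by_hand, logrank_by_hand


# stratification ------------------------------------------------------------


def test_quartile_split_on_1_to_8():
    values = pd.Series(range(1, 9), index=[f"s{i}" for i in range(1, 9)], dtype=float)
    g = stratify_by_quantile(values, q=0.25)
    assert set(g.low) == {"s1", "s2"} and set(g.high) == {"s7", "s8"}


def test_median_split_covers_everyone():
    values = pd.Series(range(1, 9), index=[f"s{i}" for i in range(1, 9)], dtype=float)
    g = stratify_by_quantile(values, q=0.5)
    assert set(g.low) | set(g.high) == set(values.index)
    assert set(g.low) & set(g.high) == set()


def test_group_sizes_match_sort_and_slice_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(8, 60))
        values = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        g = stratify_by_quantile(values, q=0.25)
        sorted_vals = np.sort(values.to_numpy())
        c_low, c_high = np.quantile(values, 0.25), np.quantile(values, 0.75)
        assert len(g.low) == int(np.sum(sorted_vals <= c_low))
        assert len(g.high) == int(np.sum(sorted_vals >= c_high))
        assert set(g.low).isdisjoint(g.high)


def test_constant_expression_rejected():
    values = pd.Series([2.0] * 8, index=[f"s{i}" for i in range(8)])
    with pytest.raises(ValueError, match="identical"):
        stratify_by_quantile(values)


# Kaplan-Meier --------------------------------------------------------------


def test_km_all_events_closed_form():
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert km.at(0.5) == 1.0 and km.at(2.5) == pytest.approx(1 / 3)


def test_km_all_censored_is_flat_one():
    km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert km.event_times.size == 0 and km.at(100.0) == 1.0


def test_km_mixed_toy_matches_hand_calculation(rng):
    times = [3, 5, 5, 7, 8, 10, 12, 12, 14, 20]
    events = [1, 1, 0, 1, 0, 1, 1, 1, 0, 0]
    km = km_estimate(times, events)
    hand = km_by_hand(times, events)
    assert np.allclose(km.event_times, [t for t, _ in hand])
    assert np.allclose(km.survival, [s for _, s in hand])


def test_km_no_censoring_equals_empirical_survival(rng):
    times = rng.exponential(10.0, 40)
    km = km_estimate(times, np.ones(40, int))
    for t in np.quantile(times, [0.2, 0.5, 0.8]):
        assert km.at(t) == pytest.approx(np.mean(times > t))


def test_km_curve_monotone_in_unit_interval(rng):
    times = rng.exponential(5.0, 60)
    events = rng.integers(0, 2, 60)
    if events.sum() == 0:
        events[0] = 1
    km = km_estimate(times, events)
    assert np.all(np.diff(km.survival) <= 1e-15)
    assert np.all((km.survival >= 0) & (km.survival <= 1))


# log-rank ------------------------------------------------------------------


def test_logrank_identical_groups_is_null():
    a = toy_survival([1, 2, 3, 4], [1, 0, 1, 1])
    chi2, p = logrank_test(a, a)
    assert chi2 == 0.0 and p == 1.0


def test_logrank_toy_matches_hand_tabulation():
    ta, ea = [6, 7, 10, 15, 19, 25], [1, 0, 1, 1, 0, 1]
    tb, eb = [4, 6, 8, 9, 12, 22], [1, 1, 0, 1, 1, 1]
    chi2, _ = logrank_test(toy_survival(ta, ea), toy_survival(tb, eb))
    assert chi2 == pytest.approx(logrank_by_hand(ta, ea, tb, eb), abs=1e-12)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    for _ in range(20):
        n = int(rng.integers(20, 60))
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.02 * np.exp(0.5 * x)))
        e = (t <= rng.exponential(60, n)).astype(int)
        t = np.minimum(t, 60.0)
        if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
            continue
        a = toy_survival(t[x == 1], e[x == 1])
        b = toy_survival(t[x == 0], e[x == 0])
        chi2, p = logrank_test(a, b)
        ref = ll_logrank(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
        assert p == pytest.approx(ref.p_value, abs=1e-6)


def test_logrank_symmetric_under_label_swap(rng):
    a = toy_survival(rng.exponential(10, 15), rng.integers(0, 2, 15) | 1)
    b = toy_survival(rng.exponential(5, 15), rng.integers(0, 2, 15) | 1,
                     index=[f"t{i}" for i in range(15)])
    assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], abs=1e-12)


def test_logrank_power_under_planted_hazard(rng):
    hits = 0
    for rep in range(100):
        x = np.zeros(200, bool)
        x[:100] = True
        t, e = sd.simulate_survival_times(x, math.log(3.0), 0.01, 0.2, rng)
        a = toy_survival(t[x], e[x])
        b = toy_survival(t[~x], e[~x], index=[f"u{i}" for i in range(100)])
        hits += logrank_test(a, b)[1] < 0.01
    assert hits >= 95


# Cox -----------------------------------------------------------------------


def cox_on_arrays(t, e, x):
    idx = [f"s{i}" for i in range(len(t))]
    surv = toy_survival(t, e, index=idx)
    return cox_hr(surv, pd.Series(x, index=idx))


def test_cox_label_swap_negates_loghr(rng):
    x = rng.integers(0, 2, 60)
    t, e = sd.simulate_survival_times(x.astype(bool), 0.7, 0.01, 0.2, rng)
    res = cox_on_arrays(t, e, x)
    res_swapped = cox_on_arrays(t, e, 1 - x)
    assert res.log_hr == pytest.approx(-res_swapped.log_hr, abs=1e-9)


def test_cox_matches_scikit_survival_breslow(rng):
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    checked = 0
    while checked < 20:
        n = int(rng.integers(30, 80))
        x = rng.integers(0, 2, n)
        t, e = sd.simulate_survival_times(x.astype(bool), 0.7, 0.01, 0.3, rng)
        if e.sum() < 5 or len(np.unique(x)) < 2:
            continue
        res = cox_on_arrays(t, e, x)
        y = np.array(list(zip(e.astype(bool), t)), dtype=[("e", "?"), ("t", "f8")])
        ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200).fit(
            x.reshape(-1, 1).astype(float), y
        )
        assert res.log_hr == pytest.approx(ref.coef_[0], abs=1e-6)
        checked += 1


def test_cox_null_estimates_center_on_zero(rng):
    est = []
    for _ in range(200):
        x = np.zeros(500)
        x[250:] = 1
        t, e = sd.simulate_survival_times(x.astype(bool), 0.0, 0.005, 0.2, rng)
        est.append(cox_on_arrays(t, e, x).log_hr)
    assert abs(np.mean(est)) < 0.05


def test_cox_complete_separation_flagged_not_raised():
    # all events in the exposed group, none elsewhere: monotone likelihood
    t = [1, 2, 3, 4, 50, 60, 70, 80]
    e = [1, 1, 1, 1, 0, 0, 0, 0]
    x = [1, 1, 1, 1, 0, 0, 0, 0]
    res = cox_on_arrays(t, e, x)
    assert not res.converged
    assert math.isinf(res.se) and math.isinf(res.ci95[1])


def test_cox_rejects_constant_covariate():
    with pytest.raises(ValueError, match="constant"):
        cox_on_arrays([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 1, 1])


# hazard screen -------------------------------------------------------------


def test_hazard_screen_recovers_planted_gene_and_flags_constant():
    wins = 0
    for seed in range(25):
        cfg = sd.SimConfig(
            seed=seed, n_genes=30, n_tumor=300, n_samples_survival=300,
            planted_prognostic=frozenset({"G00000"}), log_hr=math.log(2.5),
        )
        expr = sd.gen_expression(cfg)
        surv = sd.gen_survival(cfg, expr)
        result = hazard_screen(surv, list(expr.tpm.index), q=0.25)
        scored = result[result["ok"]]
        wins += scored["hr"].idxmax() == "G00000"
    assert wins >= 23  # planted prognostic gene tops the ranking

    # constant covariate gets flagged, not raised
    cfg = sd.SimConfig(seed=0, n_genes=5, n_tumor=50, n_samples_survival=50)
    expr = sd.gen_expression(cfg)
    surv = sd.gen_survival(cfg, expr)
    surv.covariates["G00000"] = 1.0
    res = hazard_screen(surv, ["G00000", "G00001"])
    assert not res.at["G00000", "ok"] and "identical" in res.at["G00000", "note"]


def test_hazard_screen_order_invariant():
    cfg = sd.SimConfig(seed=3, n_genes=8, n_tumor=60, n_samples_survival=60)
    expr = sd.gen_expression(cfg)
    surv = sd.gen_survival(cfg, expr)
    genes = list(expr.tpm.index)
    a = hazard_screen(surv, genes)
    b = hazard_screen(surv, genes[::-1]).loc[a.index]
    pd.testing.assert_frame_equal(a, b)
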