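"""Royston–Parmar fitting, AIC selection, and beyond-trial projection."""

import math

import numpy as np
import pytest
from lifelines import WeibullFitter

from oncoscreen_cea.extrapolation import (RPFitError, SplineSurvModel,
                                          annual_cost_components,
                                          extrapolate_costs,
                                          extrapolate_effects, fit_rp_model,
                                          select_by_aic)
from oncoscreen_cea.survival_effects import km_estimate

from conftest import make_records


def exponential_records(lam, n, seed, censor_at=None):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / lam, n)
    if censor_at is None:
        return make_records([(ti, 1) for ti in t])
    rows = [(min(ti, censor_at), int(ti <= censor_at)) for ti in t]
    return make_records(rows)


def weibull_model(log_scale, shape):
    """df=1 model built directly: ln H(t) = log_scale + shape * ln t."""
    return SplineSurvModel(df=1, knots=np.array([-2.0, 3.0]),
                           coefficients=np.array([log_scale, shape]),
                           loglik=0.0, aic=0.0, n_events=1,
                           data_range=(0.1, 20.0))


class TestFitRPModel:
    def test_df1_recovers_exponential_parameters(self):
        lam = 0.05
        rec = exponential_records(lam, 5000, seed=42)
        model = fit_rp_model(rec, "x", df=1)
        g0, g1 = model.coefficients
        # exponential is Weibull with shape 1; ~2 SE tolerances at n=5000
        assert g1 == pytest.approx(1.0, abs=0.03)
        assert g0 == pytest.approx(math.log(lam), abs=0.08)

    def test_df1_is_exactly_weibull(self):
        rec = exponential_records(0.08, 2000, seed=7, censor_at=15.0)
        model = fit_rp_model(rec, "x", df=1)
        wf = WeibullFitter().fit(rec["followup_time"], rec["event"])
        # lifelines: H(t) = (t/lambda_)^rho_  ->  ln H = rho ln t - rho ln lambda
        assert model.coefficients[1] == pytest.approx(wf.rho_, rel=2e-3)
        assert model.coefficients[0] == pytest.approx(-wf.rho_ * math.log(wf.lambda_),
                                                      rel=2e-3)

    def test_all_censored_raises(self):
        rec = make_records([(3.0, 0)] * 20)
        with pytest.raises(RPFitError):
            fit_rp_model(rec, "x", df=1)

    def test_survival_properties(self):
        rec = exponential_records(0.1, 800, seed=3)
        model = fit_rp_model(rec, "x", df=2)
        ts = np.linspace(0.05, 25.0, 120)
        s = model.survival(ts)
        assert np.all((s > 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)

    def test_within_range_agrees_with_km(self):
        rec = exponential_records(0.1, 3000, seed=9)
        model = fit_rp_model(rec, "x", df=1)
        curve = km_estimate(rec, "x")
        ts = np.quantile(rec["followup_time"], [0.2, 0.5, 0.8])
        sup = max(abs(float(model.survival(t)[0]) - float(curve.survival_at(t)))
                  for t in ts)
        assert sup < 0.02


class TestSelectByAIC:
    def test_single_element_grid(self):
        rec = exponential_records(0.1, 500, seed=5)
        model = select_by_aic(rec, "x", df_grid=(2,))
        assert model.df == 2

    def test_minimises_aic_over_grid(self):
        rec = exponential_records(0.1, 1000, seed=6)
        best = select_by_aic(rec, "x", df_grid=(1, 2, 3))
        for df in (1, 2, 3):
            assert best.aic <= fit_rp_model(rec, "x", df).aic + 1e-9

    def test_weibull_data_prefers_df1_in_majority(self):
        wins = 0
        reps = 30
        for r in range(reps):
            rec = exponential_records(0.15, 400, seed=100 + r)
            if select_by_aic(rec, "x", df_grid=(1, 2, 3)).df == 1:
                wins += 1
        assert wins > reps / 2

    def test_empty_grid_rejected(self):
        rec = exponential_records(0.1, 100, seed=1)
        with pytest.raises(ValueError):
            select_by_aic(rec, "x", df_grid=())


class TestExtrapolateEffects:
    def test_identical_models_give_zero_delta(self):
        rec = exponential_records(0.05, 500, seed=8, censor_at=12.0)
        model = fit_rp_model(rec, "x", df=1)
        curve = km_estimate(rec, "x")
        delta, _, _ = extrapolate_effects(model, model, curve, curve,
                                          horizon=25.0, discount_rate=0.015)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_exponential(self):
        # pure-model mode against an annual finite-sum of exponential
        # integrals: int_k^{k+1} e^{-lam t} dt = (e^{-lam k} - e^{-lam(k+1)})/lam
        lam_a, lam_b, rate = 0.02, 0.03, 0.015
        m_a = weibull_model(math.log(lam_a), 1.0)
        m_b = weibull_model(math.log(lam_b), 1.0)
        rec = make_records([(14.0, 0)] * 3)
        curve = km_estimate(rec, "x")
        delta, ly_a, ly_b = extrapolate_effects(m_a, m_b, curve, curve, 25.0,
                                                rate, trial_end=14.0, hybrid=False)
        def oracle(lam):
            return sum((1 + rate) ** -k * (math.exp(-lam * k) - math.exp(-lam * (k + 1))) / lam
                       for k in range(25))
        assert ly_a.total == pytest.approx(oracle(lam_a), abs=1e-6)
        assert delta == pytest.approx(oracle(lam_a) - oracle(lam_b), abs=1e-6)

    def test_discounting_shrinks_dominating_delta(self):
        m_a = weibull_model(math.log(0.02), 1.0)
        m_b = weibull_model(math.log(0.05), 1.0)
        rec = make_records([(14.0, 0)] * 3)
        curve = km_estimate(rec, "x")
        d15, _, _ = extrapolate_effects(m_a, m_b, curve, curve, 25.0, 0.015,
                                        trial_end=14.0, hybrid=False)
        d35, _, _ = extrapolate_effects(m_a, m_b, curve, curve, 25.0, 0.035,
                                        trial_end=14.0, hybrid=False)
        assert 0 < d35 < d15

    def test_horizon_inside_trial_rejected(self):
        rec = make_records([(14.0, 0)] * 3)
        curve = km_estimate(rec, "x")
        m = weibull_model(math.log(0.02), 1.0)
        with pytest.raises(ValueError):
            extrapolate_effects(m, m, curve, curve, horizon=10.0, trial_end=14.0)


class TestExtrapolateCosts:
    def test_equal_costs_collapse_to_survival_sum(self):
        m = weibull_model(math.log(0.04), 1.0)
        c = 80.0
        total = extrapolate_costs(m, c, c, trial_end=14.0, horizon=25.0)
        expected = c * sum(float(m.survival(float(k))[0]) for k in range(14, 25))
        assert total == pytest.approx(expected, rel=1e-12)

    def test_certain_survival_sums_survivor_cost(self):
        m = weibull_model(math.log(1e-12), 1.0)  # hazard ~ 0: S ~ 1
        total = extrapolate_costs(m, 50.0, 999.0, trial_end=14.0, horizon=25.0)
        assert total == pytest.approx(550.0, rel=1e-6)

    def test_matches_finite_sum_oracle_discounted(self):
        lam, rate = 0.05, 0.015
        m = weibull_model(math.log(lam), 1.0)
        total = extrapolate_costs(m, 40.0, 500.0, 14.0, 25.0, rate)
        oracle = sum((1 + rate) ** -k * (math.exp(-lam * (k + 1)) * 40.0 +
                     (math.exp(-lam * k) - math.exp(-lam * (k + 1))) * 500.0)
                     for k in range(14, 25))
        assert total == pytest.approx(oracle, rel=1e-9)

    def test_negative_costs_rejected(self):
        m = weibull_model(math.log(0.05), 1.0)
        with pytest.raises(ValueError):
            extrapolate_costs(m, -1.0, 0.0, 14.0, 25.0)


def test_annual_cost_components_hand_case():
    rows = [
        (3.0, 0, (100, 100, 100)),
        (2.0, 0, (100, 50, 0)),
        (1.5, 1, (0, 700, 0)),   # dies in year 1: decedent cost 700
    ]
    rec = make_records(rows, n_years=3)
    survivor, decedent = annual_cost_components(rec, "x")
    # survivor person-years: p1 y0,y1,y2 (100,100,100); p2 y0,y1 (100,50); p3 y0 (0)
    assert survivor == pytest.approx((100 + 100 + 100 + 100 + 50 + 0) / 6)
    assert decedent == pytest.approx(700.0)
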