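"""Generator: determinism, calibration, censoring structure, analytic oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from oncoscreen_cea.synthetic_trial import (ARMS, CostModel, HazardSpec,
                                            ParameterError, TrialDesign,
                                            calibrate_hazard, generate_trial,
                                            records_from_csv, records_to_csv,
                                            true_event_probability, true_rmst)


class TestGenerateTrial:
    def test_same_seed_gives_identical_records(self, small_design, strong_hazard, costs):
        a = generate_trial(small_design, strong_hazard, costs, seed=7)
        b = generate_trial(small_design, strong_hazard, costs, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, small_design, strong_hazard, costs):
        a = generate_trial(small_design, strong_hazard, costs, seed=7)
        b = generate_trial(small_design, strong_hazard, costs, seed=8)
        assert not a["followup_time"].equals(b["followup_time"])

    def test_resizing_one_arm_leaves_others_unchanged(self, small_design, strong_hazard, costs):
        a = generate_trial(small_design, strong_hazard, costs, seed=7)
        bigger = TrialDesign(n_control=small_design.n_control,
                             n_mms=small_design.n_mms * 2,
                             n_uss=small_design.n_uss)
        b = generate_trial(bigger, strong_hazard, costs, seed=7)
        for arm in ("control", "uss"):
            pd.testing.assert_frame_equal(
                a[a.arm == arm].reset_index(drop=True).drop(columns="id"),
                b[b.arm == arm].reset_index(drop=True).drop(columns="id"))

    def test_no_effect_arms_have_same_event_law(self, costs):
        # with both reductions zero the arm event-time distributions are
        # identical in law: a two-sample KS test must not reject
        design = TrialDesign(n_control=8000, n_mms=8000, n_uss=100)
        hz = HazardSpec(baseline_oc_hazard=0.05, lead_time=7.0,
                        reduction_mms=0.0, reduction_uss=0.0)
        rec = generate_trial(design, hz, costs, seed=11)
        tc = rec[(rec.arm == "control") & (rec.event == 1)]["followup_time"]
        tm = rec[(rec.arm == "mms") & (rec.event == 1)]["followup_time"]
        assert stats.ks_2samp(tc, tm).pvalue > 0.01

    def test_zero_recruitment_window_gives_common_censoring(self, strong_hazard, costs):
        design = TrialDesign(n_control=500, n_mms=200, n_uss=200,
                             recruitment_window=0.0)
        rec = generate_trial(design, strong_hazard, costs, seed=3)
        censored = rec[rec.event == 0]
        assert np.allclose(censored["followup_time"], design.max_followup)

    def test_followup_within_entry_window(self, small_design, strong_hazard, costs):
        rec = generate_trial(small_design, strong_hazard, costs, seed=5)
        assert (rec.followup_time > 0).all()
        assert (rec.followup_time <= small_design.max_followup + 1e-12).all()
        censored = rec[rec.event == 0]
        assert (censored.followup_time >= small_design.min_followup - 1e-12).all()

    def test_screened_arm_costs_dominate_control(self, small_design, strong_hazard, costs):
        rec = generate_trial(small_design, strong_hazard, costs, seed=9)
        cols = [c for c in rec.columns if c.startswith("cost_y")]
        totals = rec.groupby("arm")[cols].sum().sum(axis=1) / rec.groupby("arm").size()
        assert totals["mms"] >= totals["control"]
        assert totals["uss"] >= totals["control"]

    def test_costs_only_within_followup_years(self, small_design, strong_hazard, costs):
        rec = generate_trial(small_design, strong_hazard, costs, seed=9)
        cols = [c for c in rec.columns if c.startswith("cost_y")]
        arr = rec[cols].to_numpy()
        years = np.arange(arr.shape[1])
        beyond = years[None, :] >= np.ceil(rec.followup_time.to_numpy())[:, None]
        assert np.all(arr[beyond] == 0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            TrialDesign(n_control=0, n_mms=1, n_uss=1)
        with pytest.raises(ParameterError):
            HazardSpec(baseline_oc_hazard=-0.1)
        with pytest.raises(ParameterError):
            HazardSpec(baseline_oc_hazard=0.1, reduction_mms=1.0)
        with pytest.raises(ParameterError):
            CostModel(test_cost=-1)


class TestCalibration:
    def test_expected_arm_outcomes_match_targets(self, design, hazard):
        p_ctrl = true_event_probability(design, hazard, "control")
        p_mms = true_event_probability(design, hazard, "mms")
        assert p_ctrl == pytest.approx(0.0034, abs=1e-7)
        assert 1 - p_mms / p_ctrl == pytest.approx(0.15, abs=1e-5)
        lead = hazard.lead_time
        q_ctrl = true_event_probability(design, hazard, "control", window=(lead, 14))
        q_mms = true_event_probability(design, hazard, "mms", window=(lead, 14))
        assert 1 - q_mms / q_ctrl == pytest.approx(0.23, abs=1e-5)

    def test_uss_calibration(self, design, hazard):
        p_ctrl = true_event_probability(design, hazard, "control")
        p_uss = true_event_probability(design, hazard, "uss")
        assert 1 - p_uss / p_ctrl == pytest.approx(0.11, abs=1e-5)

    def test_simulated_control_rate_near_expected(self, full_trial):
        ctrl = full_trial[full_trial.arm == "control"]
        p_hat = ctrl.event.mean()
        se = math.sqrt(0.0034 * (1 - 0.0034) / len(ctrl))
        assert abs(p_hat - 0.0034) < 3 * se


class TestTrueRMST:
    def test_certain_survival(self):
        hz = HazardSpec(baseline_oc_hazard=0.0)
        assert true_rmst(hz, "control", 10.0, 0.0) == pytest.approx(10.0)

    def test_constant_hazard_closed_form(self):
        hz = HazardSpec(baseline_oc_hazard=0.1)
        expected = (1 - math.exp(-0.5)) / 0.1
        assert true_rmst(hz, "control", 5.0, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_hazard(self):
        vals = [true_rmst(HazardSpec(baseline_oc_hazard=lam), "control", 8.0, 0.0)
                for lam in (0.0, 0.01, 0.05, 0.2)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("rate", [0.0, 0.015, 0.035])
    @pytest.mark.parametrize("arm", ["control", "mms"])
    def test_matches_numerical_quadrature(self, hazard, arm, rate):
        horizon = 13.5574
        def integrand(t):
            w = (1 + rate) ** (-math.floor(t))
            return w * math.exp(-float(hazard.cumulative(arm, t)))
        pieces = sorted({0.0, hazard.lead_time, horizon} |
                        set(float(k) for k in range(1, 14)))
        oracle = sum(integrate.quad(integrand, a, b)[0]
                     for a, b in zip(pieces[:-1], pieces[1:]))
        assert true_rmst(hazard, arm, horizon, rate) == pytest.approx(oracle, rel=1e-9)

    def test_discount_reduces_value(self, hazard):
        v0 = true_rmst(hazard, "control", 13.5, 0.0)
        v15 = true_rmst(hazard, "control", 13.5, 0.015)
        v35 = true_rmst(hazard, "control", 13.5, 0.035)
        assert v35 < v15 < v0


class TestIO:
    def test_csv_roundtrip(self, small_design, strong_hazard, costs, tmp_path):
        rec = generate_trial(small_design, strong_hazard, costs, seed=2)
        path = tmp_path / "records.csv"
        records_to_csv(rec, path)
        back = records_from_csv(path)
        pd.testing.assert_frame_equal(
            rec.reset_index(drop=True), back, check_dtype=False)
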