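"""Normalization, curve fitting, model selection, inversion and potency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfasmix import doseresponse as dr
from pfasmix import simulate as sim


def _plate(rows):
    return pd.DataFrame(rows, columns=["experiment_id", "treatment_id", "compound",
                                       "concentration_uM", "eb_id",
                                       "luminescence_rlu"])


class TestNormalizeToControls:
    def test_worked_arithmetic(self):
        rows = [("E1", "control", "", 0.0, i + 1, lum)
                for i, lum in enumerate([100.0, 110.0, 90.0])]
        rows.append(("E1", "X@1uM", "X", 1.0, 1, 80.0))
        effects = dr.normalize_to_controls(_plate(rows))
        treated = effects[effects["concentration"] > 0]
        assert treated["effect"].item() == pytest.approx(0.20)

    def test_reading_at_control_mean_is_zero_effect(self):
        rows = [("E1", "control", "", 0.0, 1, 100.0),
                ("E1", "X@1uM", "X", 1.0, 1, 100.0)]
        effects = dr.normalize_to_controls(_plate(rows))
        assert effects.loc[effects["concentration"] > 0, "effect"].item() == 0.0

    def test_scale_invariance_across_experiments(self):
        rows = []
        for exp, scale in (("E1", 1.0), ("E2", 2.0)):
            rows += [(exp, "control", "", 0.0, i + 1, scale * lum)
                     for i, lum in enumerate([95.0, 100.0, 105.0])]
            rows += [(exp, "X@1uM", "X", 1.0, 1, scale * 80.0)]
        effects = dr.normalize_to_controls(_plate(rows))
        treated = effects[effects["concentration"] > 0]
        e1, e2 = treated.sort_values("experiment_id")["effect"]
        assert e1 == pytest.approx(e2, abs=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    def test_rescaling_one_experiment_leaves_effects_unchanged(self, scale):
        rows = [("E1", "control", "", 0.0, i + 1, lum)
                for i, lum in enumerate([95.0, 100.0, 105.0])]
        rows.append(("E1", "X@1uM", "X", 1.0, 1, 70.0))
        base = dr.normalize_to_controls(_plate(rows))
        scaled_rows = [(e, t, c, conc, eb, lum * scale)
                       for e, t, c, conc, eb, lum in rows]
        scaled = dr.normalize_to_controls(_plate(scaled_rows))
        np.testing.assert_allclose(scaled["effect"], base["effect"], atol=1e-12)

    def test_experiment_without_controls_raises(self):
        rows = [("E1", "X@1uM", "X", 1.0, 1, 80.0)]
        with pytest.raises(dr.MissingControlError, match="E1"):
            dr.normalize_to_controls(_plate(rows))


def _noiseless_effects(theta, family="logit", grid=None):
    grid = np.geomspace(0.1, 200, 8) if grid is None else np.asarray(grid)
    curve = dr.SigmoidCurve(family=family, theta=tuple(theta))
    return pd.DataFrame({
        "experiment_id": "E1", "treatment_id": "t",
        "concentration": np.repeat(grid, 3),
        "effect": np.repeat(curve.predict(grid), 3),
    })


class TestFitCurve:
    @pytest.mark.parametrize("family,theta", [
        ("logit", (-2.0, 2.0)),
        ("probit", (-1.5, 1.2)),
        ("weibull", (-2.5, 1.8)),
        ("generalized-logit", (-2.0, 2.5, 0.8)),
    ])
    def test_noiseless_parameter_recovery(self, family, theta):
        effects = _noiseless_effects(theta, family=family)
        res = dr.fit_curve(effects, family=family)
        assert res.converged
        assert res.theta == pytest.approx(theta, abs=1e-6)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_refit_on_own_fitted_values_is_self_consistent(self, presets,
                                                           default_noise):
        df = sim.simulate_compound_experiment(presets["PFOS"], noise=default_noise,
                                              seed=3)
        first = dr.fit_curve(dr.normalize_to_controls(df), family="logit")
        refit_data = _noiseless_effects(first.theta, family="logit",
                                        grid=np.geomspace(0.1, 60, 8))
        second = dr.fit_curve(refit_data, family="logit")
        assert second.theta == pytest.approx(first.theta, abs=1e-6)

    def test_flat_data_yields_degenerate_slope_or_failure(self):
        effects = pd.DataFrame({
            "experiment_id": "E1", "treatment_id": "t",
            "concentration": np.geomspace(0.1, 100, 8), "effect": 0.0})
        res = dr.fit_curve(effects, family="logit")
        if res.converged:
            # effect stays flat across the tested range
            span = np.ptp(res.predict(np.geomspace(0.1, 100, 50)))
            assert span < 1e-3

    def test_too_few_concentrations_rejected(self):
        effects = pd.DataFrame({
            "experiment_id": "E1", "treatment_id": "t",
            "concentration": [1.0, 2.0, 4.0], "effect": [0.1, 0.2, 0.4]})
        with pytest.raises(ValueError, match="4 distinct"):
            dr.fit_curve(effects)


class TestSelectBestFit:
    def test_single_candidate_returned(self):
        res = dr.fit_curve(_noiseless_effects((-2.0, 2.0)), family="logit")
        assert dr.select_best_fit([res]) is res

    def test_noiseless_logit_data_selects_logit_family(self):
        best, fits = dr.fit_best(_noiseless_effects((-2.0, 2.0)))
        assert best.aicc == min(f.aicc for f in fits if f.converged)
        assert best.family == "logit"  # AICc tie resolved by the family order

    def test_unconverged_candidates_never_selected(self):
        good = dr.fit_curve(_noiseless_effects((-2.0, 2.0)), family="logit")
        bad = dr.DoseResponseResults(family="probit", theta=(0.0, 1.0),
                                     rss=0.0, nobs=good.nobs, converged=False)
        assert dr.select_best_fit([good, bad]) is good
        with pytest.raises(ValueError, match="no converged"):
            dr.select_best_fit([bad])


class TestInversion:
    def test_ic50_closed_form(self):
        curve = dr.SigmoidCurve(family="logit", theta=(-2.0, 2.0))
        assert curve.invert(0.50) == pytest.approx(10.0, rel=1e-12)

    def test_ic10_closed_form_matches_root_finding(self):
        from scipy.optimize import brentq

        curve = dr.SigmoidCurve(family="logit", theta=(-2.0, 2.0))
        closed = curve.invert(0.10)
        assert closed == pytest.approx(10 ** ((np.log(1 / 9) + 2) / 2), rel=1e-10)
        assert closed == pytest.approx(0.797, abs=5e-4)
        rooted = brentq(lambda c: curve.predict(c) - 0.10, 1e-6, 1e6, xtol=1e-12)
        assert closed == pytest.approx(rooted, rel=1e-8)

    def test_unattainable_effect_rejected(self):
        curve = dr.SigmoidCurve(family="generalized-logit", theta=(-2.0, 2.0, 0.8))
        with pytest.raises(dr.UnattainableEffectError):
            curve.invert(0.99)

    @pytest.mark.parametrize("family,theta", [
        ("logit", (-2.0, 2.0)),
        ("probit", (-1.5, 1.2)),
        ("weibull", (-2.5, 1.8)),
        ("generalized-logit", (-2.0, 2.5, 0.8)),
    ])
    def test_invert_then_evaluate_is_identity(self, family, theta):
        curve = dr.SigmoidCurve(family=family, theta=theta)
        levels = np.linspace(0.01, 0.99, 41) * curve.max_effect
        levels = levels[(levels > 0) & (levels < curve.max_effect)]
        np.testing.assert_allclose(curve.predict(curve.invert(levels)), levels,
                                   atol=1e-8)


class TestBenchmark:
    def test_preset_bmc_matches_calibration_anchor(self, presets):
        for compound, p in presets.items():
            effects = _noiseless_effects(p.theta, grid=p.concentration_grid)
            res = dr.fit_curve(effects, family="logit")
            est = res.bmc(bmr=0.10)
            assert est.bmc == pytest.approx(p.bmc10_true, rel=1e-6)
            assert res.invert(0.50) == pytest.approx(p.ic50_true, rel=1e-6)

    def test_extrapolation_flag(self):
        curve_res = dr.fit_curve(_noiseless_effects((-2.0, 2.0),
                                                    grid=np.geomspace(5, 200, 8)))
        est = curve_res.bmc(bmr=0.10)  # BMC10 ~ 0.797, below the tested range
        assert est.extrapolated
        in_range = curve_res.bmc(bmr=0.10, tested_range=(0.1, 200))
        assert not in_range.extrapolated


class TestRelativePotency:
    def test_ic50_based_rpfs_match_printed_ratios(self):
        rpf = dr.relative_potency(sim.REFERENCE_IC50_UM, reference="PFOA")
        rounded = {k: round(v, 1) for k, v in rpf.items()}
        assert rounded == {"PFOA": 1.0, "PFNA": 5.2, "PFOS": 2.9, "PFHxS": 0.4}

    def test_bmc10_based_rpfs_match_printed_ratios(self):
        rpf = dr.relative_potency(sim.REFERENCE_BMC10_UM, reference="PFOA")
        rounded = {k: round(v, 1) for k, v in rpf.items()}
        assert rounded == {"PFOA": 1.0, "PFNA": 2.3, "PFOS": 1.8, "PFHxS": 0.8}

    def test_equal_values_give_unit_rpfs(self):
        rpf = dr.relative_potency({"a": 5.0, "b": 5.0, "c": 5.0}, reference="a")
        assert all(v == 1.0 for v in rpf.values())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(KeyError):
            dr.relative_potency({"a": 1.0}, reference="b")
        with pytest.raises(ValueError):
            dr.relative_potency({"a": 1.0, "b": 0.0}, reference="a")
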