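"""Bootstrap ensembles, Monte-Carlo bands and the non-overlap rule."""

import numpy as np
import pandas as pd
import pytest

from pfasmix import doseresponse as dr
from pfasmix import mixture as mx
from pfasmix import simulate as sim
from pfasmix import uncertainty as unc


def _fit(preset, noise, seed, family=None):
    df = sim.simulate_compound_experiment(preset, noise=noise, seed=seed)
    effects = dr.normalize_to_controls(df)
    if family:
        return dr.fit_curve(effects, family=family)
    best, _ = dr.fit_best(effects)
    return best


class TestParametricBootstrap:
    def test_zero_residual_variance_degenerates_to_parent(self, presets, zero_noise):
        parent = _fit(presets["PFNA"], zero_noise, seed=0, family="logit")
        assert parent.residual_scale == pytest.approx(0.0, abs=1e-12)
        ens = unc.parametric_bootstrap(parent, n_boot=25, seed=0)
        assert len(ens.members) == 25
        assert all(m.theta == parent.theta for m in ens.members)

    def test_fixed_seed_reproducible(self, presets, default_noise):
        parent = _fit(presets["PFOS"], default_noise, seed=5)
        a = unc.parametric_bootstrap(parent, n_boot=40, seed=11)
        b = unc.parametric_bootstrap(parent, n_boot=40, seed=11)
        c = unc.parametric_bootstrap(parent, n_boot=40, seed=12)
        assert [m.theta for m in a.members] == [m.theta for m in b.members]
        assert [m.theta for m in a.members] != [m.theta for m in c.members]

    def test_failures_counted_never_dropped_silently(self, presets, default_noise):
        parent = _fit(presets["PFOA"], default_noise, seed=2)
        ens = unc.parametric_bootstrap(parent, n_boot=60, seed=3)
        assert len(ens.members) + ens.n_failed == 60

    def test_non_converged_parent_rejected(self, presets):
        bad = dr.DoseResponseResults(family="logit", theta=(0.0, 1.0), rss=1.0,
                                     nobs=8, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            unc.parametric_bootstrap(bad, n_boot=5, seed=0)

    def test_ensemble_brackets_parent_bmc(self, presets, default_noise):
        """Bootstrap BMC10 distribution brackets the parent estimate.

        Over 50 seeded replications of the 3-experiment design the parent
        BMC10 falls inside its own ensemble's central 95% in >= 90% of
        replications.
        """
        inside = 0
        total = 50
        for rep in range(total):
            parent = _fit(presets["PFOS"], default_noise, seed=100 + rep,
                          family="logit")
            ens = unc.parametric_bootstrap(parent, n_boot=199, seed=rep)
            bmcs = [m.invert(0.10) for m in ens.members]
            lo, hi = np.percentile(bmcs, [2.5, 97.5])
            inside += bool(lo <= parent.invert(0.10) <= hi)
        assert inside >= 0.90 * total


class TestMcMixtureBand:
    def test_degenerate_ensembles_collapse_the_band(self, presets, equipotent_design,
                                                    zero_noise):
        enss = {}
        for i, comp in enumerate(equipotent_design.compounds):
            parent = _fit(presets[comp], zero_noise, seed=i, family="logit")
            enss[comp] = unc.parametric_bootstrap(parent, n_boot=30, seed=i)
        grid = equipotent_design.total_at(np.geomspace(0.05, 1.5, 9))
        band = unc.mc_mixture_band(equipotent_design, enss, "CA", grid,
                                   n_mc=50, seed=0)
        np.testing.assert_allclose(band.lower, band.point, atol=1e-12)
        np.testing.assert_allclose(band.upper, band.point, atol=1e-12)

    def test_band_orders_lower_point_upper(self, presets, equipotent_design,
                                           default_noise):
        enss = {}
        for i, comp in enumerate(equipotent_design.compounds):
            parent = _fit(presets[comp], default_noise, seed=20 + i)
            enss[comp] = unc.parametric_bootstrap(parent, n_boot=120, seed=i)
        grid = equipotent_design.total_at(np.geomspace(0.05, 1.5, 9))
        for model in ("CA", "IA"):
            band = unc.mc_mixture_band(equipotent_design, enss, model, grid,
                                       n_mc=200, seed=1)
            assert np.all(band.lower <= band.upper)
            assert np.all((band.lower >= 0) & (band.upper <= 1))

    def test_single_draw_band_collapses_to_that_draw(self, presets,
                                                     equipotent_design,
                                                     default_noise):
        enss = {}
        for i, comp in enumerate(equipotent_design.compounds):
            parent = _fit(presets[comp], default_noise, seed=30 + i)
            enss[comp] = unc.parametric_bootstrap(parent, n_boot=50, seed=i)
        grid = equipotent_design.total_at(np.array([0.25, 1.0]))
        band = unc.mc_mixture_band(equipotent_design, enss, "CA", grid,
                                   n_mc=1, seed=4)
        np.testing.assert_allclose(band.lower, band.upper, atol=1e-12)

    def test_band_reproducible_under_fixed_seeds(self, presets, equipotent_design,
                                                 default_noise):
        def build():
            enss = {}
            for i, comp in enumerate(equipotent_design.compounds):
                parent = _fit(presets[comp], default_noise, seed=40 + i)
                enss[comp] = unc.parametric_bootstrap(parent, n_boot=60, seed=i)
            grid = equipotent_design.total_at(np.geomspace(0.1, 1.5, 7))
            return unc.mc_mixture_band(equipotent_design, enss, "CA", grid,
                                       n_mc=80, seed=9)

        a, b = build(), build()
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_missing_ensemble_rejected(self, presets, equipotent_design,
                                       default_noise):
        parent = _fit(presets["PFNA"], default_noise, seed=0)
        enss = {"PFNA": unc.parametric_bootstrap(parent, n_boot=10, seed=0)}
        with pytest.raises(KeyError):
            unc.mc_mixture_band(equipotent_design, enss, "CA",
                                np.array([19.625]), n_mc=5, seed=0)

    def test_wider_residual_scale_never_narrows_the_band(self, presets,
                                                         equipotent_design):
        """Band width at the BMR node grows along a noise ladder."""
        grid = np.array([19.625])
        widths = []
        for sigma in (0.02, 0.05, 0.10):
            noise = sim.NoiseModel(sigma_within=sigma, sigma_between=0.0, seed=0)
            enss = {}
            for i, comp in enumerate(equipotent_design.compounds):
                parent = _fit(presets[comp], noise, seed=50 + i, family="logit")
                enss[comp] = unc.parametric_bootstrap(parent, n_boot=150, seed=i)
            band = unc.mc_mixture_band(equipotent_design, enss, "CA", grid,
                                       n_mc=2000, seed=3)
            widths.append(float(band.upper[0] - band.lower[0]))
        assert widths[0] <= widths[1] + 0.01
        assert widths[1] <= widths[2] + 0.01


def _band(grid, lower, upper, model="observed"):
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    return unc.PredictionBand(model=model, grid=np.asarray(grid, dtype=float),
                              lower=lower, point=(lower + upper) / 2, upper=upper)


class TestCompareBands:
    def test_identical_bands_never_significant(self):
        grid = np.geomspace(1, 100, 8)
        band = _band(grid, np.linspace(0.01, 0.5, 8), np.linspace(0.05, 0.6, 8))
        report = unc.compare_bands(band, band)
        assert not report.any_significant

    def test_fully_separated_bands_significant_everywhere(self):
        grid = np.geomspace(1, 100, 8)
        low = _band(grid, np.full(8, 0.05), np.full(8, 0.10))
        high = _band(grid, np.full(8, 0.30), np.full(8, 0.40))
        report = unc.compare_bands(low, high)
        assert report.any_significant
        assert report.n_significant == len(report.grid)
        assert report.ranges[0] == (pytest.approx(1.0), pytest.approx(100.0))

    def test_symmetric_in_arguments(self):
        a = _band(np.geomspace(1, 100, 9), np.linspace(0.0, 0.4, 9),
                  np.linspace(0.1, 0.5, 9))
        b = _band(np.geomspace(2, 80, 6), np.linspace(0.2, 0.6, 6),
                  np.linspace(0.3, 0.7, 6))
        ab = unc.compare_bands(a, b)
        ba = unc.compare_bands(b, a)
        np.testing.assert_array_equal(ab.grid, ba.grid)
        np.testing.assert_array_equal(ab.significant, ba.significant)

    def test_disjoint_grids_rejected(self):
        a = _band(np.array([1.0, 2.0]), [0.1, 0.1], [0.2, 0.2])
        b = _band(np.array([10.0, 20.0]), [0.1, 0.1], [0.2, 0.2])
        with pytest.raises(ValueError, match="no concentration range"):
            unc.compare_bands(a, b)

    def test_detects_ia_truth_against_ca_prediction(self, zero_noise):
        """Steep, well-separated curves: the CA-IA gap exceeds tight bands."""
        presets = {
            "A": sim.calibrate_preset("A", 10.0, 14.0,
                                      concentration_grid=np.geomspace(1, 60, 8)),
            "B": sim.calibrate_preset("B", 12.0, 17.0,
                                      concentration_grid=np.geomspace(1, 60, 8)),
        }
        design = mx.build_design({"A": 10.0, "B": 12.0}, mixture_id="two")
        tiny = sim.NoiseModel(sigma_within=0.01, sigma_between=0.0, seed=0)
        enss = {}
        for i, comp in enumerate(design.compounds):
            parent = _fit(presets[comp], tiny, seed=60 + i, family="logit")
            enss[comp] = unc.parametric_bootstrap(parent, n_boot=150, seed=i)
        grid = design.total_at(np.geomspace(0.3, 1.6, 10))
        ca_band = unc.mc_mixture_band(design, enss, "CA", grid, n_mc=300, seed=2)

        observed = sim.simulate_mixture_experiment(
            design, presets, truth_model="IA",
            enrichment_grid=np.geomspace(0.1, 1.6, 8), noise=tiny, seed=99)
        ob = dr.fit_best(dr.normalize_to_controls(observed))[0]
        oens = unc.parametric_bootstrap(ob, n_boot=150, seed=7)
        oband = unc.ensemble_band(oens, grid)
        report = unc.compare_bands(oband, ca_band)
        assert report.any_significant
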