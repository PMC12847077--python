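"""End-to-end study workflows shared by the acceptance checks and the CLI.

These functions compose the library modules into the two simulation
studies the package is validated with:

* :func:`bmc_recovery_study` - repeated simulate-fit-invert rounds per
  compound, summarizing how well the benchmark concentration of each
  calibrated truth curve is recovered under the assay design (3
  experiments x 6 EBs x 8 concentrations) at default noise.
* :func:`ca_band_study` - synthetic "worlds" with a concentration-addition
  truth: component datasets are fitted and bootstrapped, the CA 95% band is
  propagated by Monte Carlo, and an observed equipotent-mixture dataset is
  fitted, bootstrapped and compared against the prediction with the
  band-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import doseresponse as dr
from . import mixture as mx
from . import simulate as sim
from . import uncertainty as unc

__all__ = ["bmc_recovery_study", "ca_band_study", "CaBandWorld"]


def bmc_recovery_study(n_replications: int = 100, seed: int = 0,
                       noise: sim.NoiseModel | None = None,
                       presets: dict | None = None) -> dict:
    """Median recovered BMC10 per compound over seeded replications.

    Each replication simulates the full single-compound design, normalizes
    to controls, fits the best-fit suite and inverts the winner at the 10%
    benchmark response.  Replications where the BMR is unattainable for
    the selected curve are counted, not silently dropped.
    """
    presets = presets or sim.default_presets()
    noise = noise or sim.NoiseModel()
    out = {}
    for k, compound in enumerate(sorted(presets)):
        preset = presets[compound]
        estimates, n_unattainable = [], 0
        for rep in range(n_replications):
            rep_seed = seed + 100_000 * k + rep
            records = sim.simulate_compound_experiment(preset, noise=noise,
                                                       seed=rep_seed)
            best, _ = dr.fit_best(dr.normalize_to_controls(records))
            try:
                estimates.append(best.bmc(bmr=0.10).bmc)
            except dr.UnattainableEffectError:
                n_unattainable += 1
        out[compound] = {
            "median_bmc10": float(np.median(estimates)),
            "truth_bmc10": preset.bmc10_true,
            "n_estimates": len(estimates),
            "n_unattainable": n_unattainable,
        }
    return out


@dataclass(frozen=True)
class CaBandWorld:
    """One synthetic world of the CA band study."""

    covered_at_bmr: bool
    any_flagged: bool
    band: unc.PredictionBand
    observed_band: unc.PredictionBand


def ca_band_study(n_worlds: int = 100, seed: int = 0, n_boot: int = 300,
                  n_mc: int = 300, noise: sim.NoiseModel | None = None,
                  collect: bool = False):
    """Coverage of the CA 95% band and the false-significance rate.

    The truth is concentration addition over the four calibrated presets in
    the equipotent BMC10 design.  Per world: simulate + fit + bootstrap the
    four components, build the CA band over an enrichment grid containing
    the node where the truth passes the 10% benchmark response (total
    19.625 µM), record whether the band covers 0.10 there; then simulate an
    observed mixture under the CA truth, fit/bootstrap it and record
    whether the non-overlap rule flags any node.

    Bootstrap members re-select the model family per resample (the full
    estimation procedure), and residuals are resampled with the grouped
    per-experiment decomposition - both are needed for the band to carry
    the estimator's actual sampling variability.
    """
    presets = sim.default_presets()
    design = mx.build_design(sim.REFERENCE_BMC10_UM, mixture_id="equipotent")
    noise = noise or sim.NoiseModel()
    true_curves = {k: p.curve for k, p in presets.items()}
    c_star = mx.ca_icx(design, {k: c.invert(0.10)
                                for k, c in true_curves.items()})
    grid = np.sort(np.append(design.total_at(np.geomspace(0.02, 1.5, 12)), c_star))
    node = int(np.argmin(np.abs(grid - c_star)))

    n_covered = 0
    n_flagged = 0
    worlds = []
    for w in range(n_worlds):
        base = seed + 1000 * w
        ensembles = {}
        for i, compound in enumerate(design.compounds):
            records = sim.simulate_compound_experiment(
                presets[compound], noise=noise, seed=base + i)
            best, _ = dr.fit_best(dr.normalize_to_controls(records))
            ensembles[compound] = unc.parametric_bootstrap(
                best, n_boot=n_boot, seed=base + 10 + i,
                families=dr.FAMILY_ORDER)
        band = unc.mc_mixture_band(design, ensembles, "CA", grid,
                                   n_mc=n_mc, seed=base + 20)
        covered = bool(band.lower[node] <= 0.10 <= band.upper[node])

        observed = sim.simulate_mixture_experiment(
            design, presets, truth_model="CA", noise=noise, seed=base + 30)
        obs_fit, _ = dr.fit_best(dr.normalize_to_controls(observed))
        obs_ens = unc.parametric_bootstrap(obs_fit, n_boot=n_boot,
                                           seed=base + 40,
                                           families=dr.FAMILY_ORDER)
        obs_band = unc.ensemble_band(obs_ens, grid)
        report = unc.compare_bands(obs_band, band)

        n_covered += covered
        n_flagged += report.any_significant
        if collect:
            worlds.append(CaBandWorld(covered_at_bmr=covered,
                                      any_flagged=report.any_significant,
                                      band=band, observed_band=obs_band))
    summary = {
        "n_worlds": n_worlds,
        "coverage_percent": 100.0 * n_covered / n_worlds,
        "flagged_percent": 100.0 * n_flagged / n_worlds,
        "bmr_node_total_uM": float(grid[node]),
    }
    return (summary, worlds) if collect else summary
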