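"""Synthetic PluriLum-style datasets for single compounds and mixtures.

The generator emulates the assay design the analysis assumes: three
independent experiments, six embryoid bodies (EBs) per treatment, eight
log-spaced concentrations per compound, and control wells in every
experiment.  Component truth curves are calibrated so that their BMC10 and
IC50 equal the assay-derived anchor values for the four PFAS under study
(PFNA 10.2/16 µM, PFOS 13.2/29 µM, PFOA 23.7/83 µM, PFHxS 31.4/230 µM).

Noise model (both components configurable, zero sigmas give an exact
forward evaluation of the truth curve):

* ``sigma_between`` - a per-experiment multiplicative log-normal scale on
  raw luminescence, emulating day-to-day assay intensity drift.  Dividing
  by the within-experiment control mean removes it, which is exactly the
  job control normalization has on real plates.
* ``sigma_within`` - additive Gaussian EB-to-EB scatter on the normalized
  response, truncated so luminescence stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import SigmoidCurve, get_family
from .mixture import MixtureDesign, ca_effect_at, ia_effect

__all__ = [
    "REFERENCE_BMC10_UM",
    "REFERENCE_IC50_UM",
    "DEFAULT_CONCENTRATION_RANGES_UM",
    "NoiseModel",
    "GeneratorPreset",
    "calibrate_preset",
    "default_presets",
    "default_concentration_grid",
    "simulate_compound_experiment",
    "simulate_mixture_experiment",
    "truth_metadata",
]

#: assay-derived benchmark concentrations (10% inhibition), µM
REFERENCE_BMC10_UM = {"PFNA": 10.2, "PFOS": 13.2, "PFOA": 23.7, "PFHxS": 31.4}

#: assay-derived half-maximal inhibitory concentrations, µM
REFERENCE_IC50_UM = {"PFNA": 16.0, "PFOS": 29.0, "PFOA": 83.0, "PFHxS": 230.0}

#: tested concentration ranges per compound, µM (8-point log-spaced grids)
DEFAULT_CONCENTRATION_RANGES_UM = {
    "PFOA": (0.1, 200.0),
    "PFHxS": (0.1, 200.0),
    "PFOS": (0.1, 60.0),
    "PFNA": (0.1, 40.0),
}

DEFAULT_CONTROL_LEVEL_RLU = 1.0e4


@dataclass(frozen=True)
class NoiseModel:
    """Variance components of the generator.

    The assay publication reports no variance estimates; the defaults are
    plausible assay scatter and are recorded in the truth metadata of every
    simulated dataset so recovery tests know what they were run at.
    """

    sigma_within: float = 0.05
    sigma_between: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.sigma_within < 0 or self.sigma_between < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class GeneratorPreset:
    """A calibrated truth curve plus its concentration grid."""

    compound: str
    family: str
    theta: tuple
    bmc10_true: float
    ic50_true: float
    concentration_grid: tuple

    @property
    def curve(self) -> SigmoidCurve:
        return SigmoidCurve(family=self.family, theta=self.theta)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound, "family": self.family,
            "theta": list(map(float, self.theta)),
            "bmc10_true": self.bmc10_true, "ic50_true": self.ic50_true,
            "concentration_grid": list(map(float, self.concentration_grid)),
        }


def default_concentration_grid(compound: str, n: int = 8) -> np.ndarray:
    lo, hi = DEFAULT_CONCENTRATION_RANGES_UM[compound]
    return np.geomspace(lo, hi, n)


def calibrate_preset(compound: str, bmc10: float, ic50: float,
                     family: str = "logit", concentration_grid=None) -> GeneratorPreset:
    """Two-point calibration: solve theta so E(bmc10)=0.10 and E(ic50)=0.50.

    Closed form for any two-parameter family with an invertible CDF link:
    the link of the effect is linear in log10 concentration, so the two
    anchors give a 2x2 linear system for (theta1, theta2).
    """
    if not (0 < bmc10 < ic50):
        raise ValueError(
            "calibration requires 0 < bmc10 < ic50 (the slope would otherwise be non-positive)"
        )
    fam = get_family(family)
    if fam.n_params != 2:
        raise ValueError(f"family {fam.name!r} does not support two-point calibration")
    z10 = float(fam._link(0.10))
    z50 = float(fam._link(0.50))
    x10, x50 = np.log10(bmc10), np.log10(ic50)
    theta2 = (z50 - z10) / (x50 - x10)
    theta1 = z50 - theta2 * x50
    grid = (default_concentration_grid(compound)
            if concentration_grid is None and compound in DEFAULT_CONCENTRATION_RANGES_UM
            else concentration_grid)
    if grid is None:
        raise ValueError(f"no default concentration grid for {compound!r}; pass one")
    return GeneratorPreset(
        compound=compound, family=fam.name, theta=(theta1, theta2),
        bmc10_true=float(bmc10), ic50_true=float(ic50),
        concentration_grid=tuple(np.asarray(grid, dtype=float)),
    )


def default_presets(family: str = "logit") -> dict:
    """Calibrated presets for the four PFAS at their anchor potencies."""
    return {
        compound: calibrate_preset(
            compound, REFERENCE_BMC10_UM[compound], REFERENCE_IC50_UM[compound],
            family=family,
        )
        for compound in ("PFNA", "PFOS", "PFOA", "PFHxS")
    }


def _experiment_rows(effects_by_treatment, n_experiments, n_eb, noise,
                     control_level, rng, make_row):
    """Shared raw-luminescence generation for compound and mixture plates."""
    rows = []
    for e in range(1, n_experiments + 1):
        exp_id = f"E{e}"
        scale = float(np.exp(rng.normal(0.0, noise.sigma_between))) \
            if noise.sigma_between > 0 else 1.0
        for treatment_id, payload, effect in effects_by_treatment:
            eps = rng.normal(0.0, noise.sigma_within, size=n_eb) \
                if noise.sigma_within > 0 else np.zeros(n_eb)
            lum = control_level * scale * np.clip(1.0 - effect + eps, 1e-9, None)
            for eb in range(1, n_eb + 1):
                rows.append(make_row(exp_id, treatment_id, payload, eb, lum[eb - 1]))
    return rows


def simulate_compound_experiment(
    preset: GeneratorPreset,
    n_experiments: int = 3,
    n_eb: int = 6,
    noise: NoiseModel | None = None,
    include_controls: bool = True,
    control_level: float = DEFAULT_CONTROL_LEVEL_RLU,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate single-compound plate records (single-compound schema).

    With zero noise the per-experiment normalized mean inhibition at each
    concentration equals the preset curve value exactly.
    """
    if n_experiments < 1 or n_eb < 1:
        raise ValueError("need at least one experiment and one EB")
    grid = np.asarray(preset.concentration_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    treatments = []
    if include_controls:
        treatments.append(("control", 0.0, 0.0))
    effects = preset.curve.predict(grid)
    for c, eff in zip(grid, effects):
        treatments.append((f"{preset.compound}@{c:.6g}uM", float(c), float(eff)))

    def make_row(exp_id, treatment_id, conc, eb, lum):
        return {
            "experiment_id": exp_id, "treatment_id": treatment_id,
            "compound": preset.compound if treatment_id != "control" else "",
            "concentration_uM": conc, "eb_id": eb, "luminescence_rlu": lum,
        }

    rows = _experiment_rows(treatments, n_experiments, n_eb, noise,
                            control_level, rng, make_row)
    return pd.DataFrame(rows)


def simulate_mixture_experiment(
    design: MixtureDesign,
    presets: dict,
    truth_model: str = "CA",
    enrichment_grid=None,
    n_experiments: int = 3,
    n_eb: int = 6,
    noise: NoiseModel | None = None,
    include_controls: bool = True,
    control_level: float = DEFAULT_CONTROL_LEVEL_RLU,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate fixed-ratio mixture plate records (mixture schema).

    The truth response at each enrichment factor is the chosen
    non-interaction model (CA or IA) applied to the preset curves; with
    zero noise the normalized output reproduces it exactly.
    """
    missing = [c for c in design.compounds if c not in presets]
    if missing:
        raise KeyError(f"missing preset for mixture component(s): {missing}")
    if truth_model not in ("CA", "IA"):
        raise ValueError("truth_model must be 'CA' or 'IA'")
    if enrichment_grid is None:
        enrichment_grid = np.geomspace(0.01, 1.5, 8)
    f = np.asarray(enrichment_grid, dtype=float)
    if f.size == 0:
        raise ValueError("empty enrichment grid")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    curves = {c: presets[c].curve for c in design.compounds}
    totals = design.total_at(f)
    if truth_model == "CA":
        effects = np.atleast_1d(ca_effect_at(design, curves, totals))
    else:
        effects = np.atleast_1d(ia_effect(design, curves, totals))

    treatments = []
    if include_controls:
        treatments.append(("control", (0.0, 0.0), 0.0))
    for fac, total, eff in zip(f, totals, effects):
        treatments.append((f"{design.mixture_id}@{fac:.6g}x", (float(total), float(fac)),
                           float(eff)))

    def make_row(exp_id, treatment_id, payload, eb, lum):
        total, fac = payload
        return {
            "experiment_id": exp_id, "treatment_id": treatment_id, "compound": "",
            "concentration_uM": total, "eb_id": eb, "luminescence_rlu": lum,
            "mixture_id": design.mixture_id if treatment_id != "control" else "",
            "enrichment_factor": fac,
        }

    rows = _experiment_rows(treatments, n_experiments, n_eb, noise,
                            control_level, rng, make_row)
    return pd.DataFrame(rows)


def truth_metadata(presets, noise: NoiseModel, truth_model: str | None = None,
                   design: MixtureDesign | None = None) -> dict:
    """Machine-readable record of what a simulated dataset was drawn from."""
    meta = {
        "presets": {k: p.to_dict() for k, p in
                    (presets.items() if isinstance(presets, dict)
                     else {presets.compound: presets}.items())},
        "noise": {"sigma_within": noise.sigma_within,
                  "sigma_between": noise.sigma_between, "seed": noise.seed},
        "note": ("variance components are generator defaults, not "
                 "assay-derived estimates"),
    }
    if truth_model is not None:
        meta["truth_model"] = truth_model
    if design is not None:
        meta["design"] = design.to_dict()
    return meta
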