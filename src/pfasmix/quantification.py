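"""Protein-normalized PFAS uptake, Bradford calibration and qPCR fold change.

Cellular PFAS levels measured by LC-MS/MS (ng/mL in the cell extract) are
normalized to total protein content from a Bradford assay (µg/mL).  The
ratio is an ng PFAS / µg protein value; results default to the equivalent
pg/mg protein scale (1 ng/µg = 1e6 pg/mg).  Relative uptake ratios are
expressed against a reference compound (PFOA = 1).  The cellular fraction
estimate compares the PFAS mass recovered from pooled cells with the
nominal mass added to the exposure medium; every assumption entering the
nominal mass (medium volume, number of wells, molar mass) is an explicit
input.  qPCR fold changes use the standard 2^-ddCt quantification against
a housekeeping gene and a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "BradfordCalibration",
    "bradford_fit",
    "bradford_invert",
    "normalize_uptake",
    "relative_uptake",
    "cellular_fraction",
    "ddct_fold_change",
]

#: 1 ng/µg expressed in pg/mg
NG_PER_UG_TO_PG_PER_MG = 1.0e6


@dataclass(frozen=True)
class BradfordCalibration:
    """Linear BSA standard curve: absorbance = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standard_range: tuple  # (min, max) µg/mL covered by the standards

    def in_range(self, concentration: float) -> bool:
        lo, hi = self.standard_range
        return lo <= concentration <= hi


def bradford_fit(standards) -> BradfordCalibration:
    """Ordinary least-squares line through (concentration µg/mL, absorbance).

    Requires at least two distinct standard concentrations.
    """
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absorbance = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need standards at >= 2 distinct concentrations")
    res = stats.linregress(conc, absorbance)
    return BradfordCalibration(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standard_range=(float(conc.min()), float(conc.max())),
    )


def bradford_invert(cal: BradfordCalibration, absorbance: float):
    """Protein concentration (µg/mL) from an absorbance reading.

    Returns ``(concentration, in_range)``; predictions outside the
    standard range are flagged, not rejected.
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (float(absorbance) - cal.intercept) / cal.slope
    return conc, cal.in_range(conc)


def normalize_uptake(pfas_conc_ng_per_ml: float, protein_conc_ug_per_ml: float,
                     out_unit: str = "pg_per_mg") -> float:
    """Protein-normalized uptake from LC-MS/MS and Bradford concentrations."""
    if protein_conc_ug_per_ml <= 0:
        raise ValueError("protein concentration must be positive")
    if pfas_conc_ng_per_ml < 0:
        raise ValueError("PFAS concentration must be non-negative")
    ng_per_ug = pfas_conc_ng_per_ml / protein_conc_ug_per_ml
    if out_unit == "ng_per_ug":
        return ng_per_ug
    if out_unit == "pg_per_mg":
        return ng_per_ug * NG_PER_UG_TO_PG_PER_MG
    raise ValueError(f"unknown output unit {out_unit!r}")


def relative_uptake(means: Mapping[str, float], reference: str) -> dict:
    """Uptake ratios mean_i / mean_reference; the reference maps to exactly 1."""
    if reference not in means:
        raise KeyError(f"reference compound {reference!r} not in means")
    ref = means[reference]
    if ref <= 0:
        raise ValueError("reference uptake must be positive")
    out = {k: v / ref for k, v in means.items()}
    out[reference] = 1.0
    return out


def cellular_fraction(measured_mass_ng: float, nominal_conc_uM: float,
                      medium_volume_uL: float, n_wells: int,
                      molar_mass_g_per_mol: float) -> dict:
    """Percent of the nominally added PFAS mass recovered from the cells.

    nominal mass (ng) = conc (µmol/L) * volume (µL) * n_wells * M (g/mol) * 1e-3.
    All assumptions are explicit inputs and echoed in the returned record.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass is required and must be positive")
    if nominal_conc_uM <= 0 or medium_volume_uL <= 0 or n_wells <= 0:
        raise ValueError("nominal concentration, volume and well count must be positive")
    if measured_mass_ng < 0:
        raise ValueError("measured mass must be non-negative")
    nominal_mass_ng = (nominal_conc_uM * medium_volume_uL * n_wells
                       * molar_mass_g_per_mol * 1e-3)
    return {
        "fraction_percent": 100.0 * measured_mass_ng / nominal_mass_ng,
        "measured_mass_ng": float(measured_mass_ng),
        "nominal_mass_ng": float(nominal_mass_ng),
        "nominal_conc_uM": float(nominal_conc_uM),
        "medium_volume_uL": float(medium_volume_uL),
        "n_wells": int(n_wells),
        "molar_mass_g_per_mol": float(molar_mass_g_per_mol),
    }


def ddct_fold_change(ct_target_treated: float, ct_hk_treated: float,
                     ct_target_control: float, ct_hk_control: float) -> float:
    """Relative expression by the 2^-ddCt method (Livak).

    ddCt = (Ct_target - Ct_housekeeping)_treated
         - (Ct_target - Ct_housekeeping)_control.
    """
    cts = (ct_target_treated, ct_hk_treated, ct_target_control, ct_hk_control)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_hk_treated) - (ct_target_control - ct_hk_control)
    return float(2.0 ** (-ddct))
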