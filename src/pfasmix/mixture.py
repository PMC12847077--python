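"""Fixed-ratio mixture designs and CA / IA mixture-effect prediction.

Two classical non-interaction models are implemented for a mixture of n
components with mole fractions p_i (sum 1) on a total-concentration axis:

Concentration addition (CA)::

    ICx_mixture = [ sum_i p_i / ICx_i ]^-1

where ICx_i is the concentration of component i alone producing the x
inhibition.  CA is explicit in *effect* space: for each effect level x the
component curves are inverted and combined, tracing the (concentration,
effect) locus of the predicted mixture curve.

Independent action (IA)::

    E(c_mixture) = 1 - prod_i (1 - E(c_i)),   c_i = p_i * c_mixture

where E(c_i) is component i's own concentration-response curve evaluated at
its share of the total concentration.

A fixed-ratio design also carries an enrichment-factor axis: enrichment 1
corresponds to the design's reference total concentration (for the
equipotent design, the sum of the component BMC10 values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "UNIT_TO_UM",
    "MixtureDesign",
    "MixtureCurve",
    "build_design",
    "ca_icx",
    "ca_curve",
    "ca_effect_at",
    "ia_effect",
    "ia_curve",
    "default_effect_grid",
    "ADULT_SERUM_NM",
    "CHILDREN_SERUM_NM",
]

#: conversion factors to the internal concentration unit (µM)
UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6}

#: average European adult serum concentrations (nM) used for the adult
#: "real-life" fixed-ratio mixture (enrichment factor 1 = these levels).
ADULT_SERUM_NM = {"PFOS": 15.0, "PFHxS": 12.3, "PFOA": 5.1, "PFNA": 1.6}

#: average European children serum concentrations (nM).
CHILDREN_SERUM_NM = {"PFOS": 6.6, "PFHxS": 1.4, "PFOA": 8.0, "PFNA": 2.0}


@dataclass(frozen=True)
class MixtureDesign:
    """A fixed-ratio mixture: components, mole fractions, enrichment basis.

    ``reference_concentrations`` (µM) are the component concentrations at
    enrichment factor 1; mole fractions are proportional to them and the
    enrichment basis is their sum.
    """

    mixture_id: str
    compounds: tuple
    reference_concentrations: tuple

    def __post_init__(self):
        if len(self.compounds) != len(self.reference_concentrations):
            raise ValueError("component/concentration length mismatch")
        if len(self.compounds) < 1:
            raise ValueError("a design needs at least one component")
        if any(c <= 0 for c in self.reference_concentrations):
            raise ValueError("reference concentrations must be positive")

    @property
    def basis_total(self) -> float:
        """Total concentration (µM) at enrichment factor 1."""
        return float(sum(self.reference_concentrations))

    @property
    def mole_fractions(self) -> np.ndarray:
        conc = np.asarray(self.reference_concentrations, dtype=float)
        return conc / conc.sum()

    def fractions(self) -> dict:
        return dict(zip(self.compounds, self.mole_fractions))

    def total_at(self, enrichment):
        """Total mixture concentration (µM) at an enrichment factor."""
        return np.asarray(enrichment, dtype=float) * self.basis_total

    def enrichment_of(self, total):
        """Enrichment factor corresponding to a total concentration (µM)."""
        return np.asarray(total, dtype=float) / self.basis_total

    def to_dict(self) -> dict:
        return {
            "mixture_id": self.mixture_id,
            "compounds": list(self.compounds),
            "reference_concentrations_uM": list(map(float, self.reference_concentrations)),
        }

    @classmethod
    def from_dict(cls, d) -> "MixtureDesign":
        return cls(
            mixture_id=d["mixture_id"],
            compounds=tuple(d["compounds"]),
            reference_concentrations=tuple(d["reference_concentrations_uM"]),
        )


def build_design(values: Mapping, mixture_id: str = "mixture",
                 unit: str = "uM") -> MixtureDesign:
    """Build a fixed-ratio design from component concentrations.

    ``values`` maps compound -> concentration, either plain numbers in
    ``unit`` or per-component ``(value, unit)`` pairs (the serum-derived
    designs are stated in nM; everything is harmonized to µM internally).
    """
    if len(values) < 1:
        raise ValueError("empty component table")
    compounds, concs = [], []
    for compound, val in values.items():
        if isinstance(val, (tuple, list)):
            v, u = val
        else:
            v, u = val, unit
        if u not in UNIT_TO_UM:
            raise ValueError(f"unknown concentration unit {u!r} for {compound!r}")
        compounds.append(compound)
        concs.append(float(v) * UNIT_TO_UM[u])
    return MixtureDesign(mixture_id=mixture_id, compounds=tuple(compounds),
                         reference_concentrations=tuple(concs))


@dataclass(frozen=True)
class MixtureCurve:
    """Predicted mixture response: (total concentration, effect) locus."""

    model: str  # "CA" or "IA"
    total_concentration: np.ndarray
    effects: np.ndarray
    design: MixtureDesign | None = None

    @property
    def enrichment(self) -> np.ndarray:
        if self.design is None:
            raise ValueError("curve carries no design; no enrichment axis")
        return self.design.enrichment_of(self.total_concentration)


def default_effect_grid(lo: float = 0.005, hi: float = 0.95, n: int = 200) -> np.ndarray:
    """Effect levels log-spaced in odds, dense near the BMR."""
    from scipy.special import expit, logit

    return expit(np.linspace(logit(lo), logit(hi), n))


def _check_components(design: MixtureDesign, mapping: Mapping, what: str):
    missing = [c for c in design.compounds if c not in mapping]
    if missing:
        raise KeyError(f"missing {what} for mixture component(s): {missing}")


# --------------------------------------------------------------------------
# concentration addition


def ca_icx(design: MixtureDesign, icx_components: Mapping[str, float]) -> float:
    """CA mixture ICx from component ICx values: [sum p_i/ICx_i]^-1."""
    _check_components(design, icx_components, "ICx")
    p = design.mole_fractions
    icx = np.array([icx_components[c] for c in design.compounds], dtype=float)
    if np.any(icx <= 0):
        raise ValueError("component ICx values must be positive")
    return float(1.0 / np.sum(p / icx))


def _attainable_max(design: MixtureDesign, curves: Mapping) -> float:
    return min(curves[c].max_effect for c in design.compounds)


def ca_curve(design: MixtureDesign, curves: Mapping, effect_grid=None) -> MixtureCurve:
    """CA-predicted mixture curve by effect-space traversal.

    For each effect level x the component curves are inverted in closed
    form and combined via the CA sum.  Effect levels at or above the least
    attainable component maximum are truncated with a warning.
    """
    _check_components(design, curves, "fitted curve")
    x = np.asarray(default_effect_grid() if effect_grid is None else effect_grid,
                   dtype=float)
    emax = _attainable_max(design, curves)
    keep = x < emax * (1 - 1e-12)
    if not np.all(keep):
        warnings.warn(
            f"effect grid truncated at the least attainable component maximum ({emax:g})",
            RuntimeWarning, stacklevel=2,
        )
        x = x[keep]
    p = design.mole_fractions
    denom = np.zeros_like(x)
    for frac, compound in zip(p, design.compounds):
        denom += frac / curves[compound].invert(x)
    return MixtureCurve(model="CA", total_concentration=1.0 / denom,
                        effects=x, design=design)


def ca_effect_at(design: MixtureDesign, curves: Mapping, total_concentration,
                 *, n_iter: int = 80) -> np.ndarray:
    """CA-predicted effect at given total concentration(s).

    Inverts the explicit effect -> ICx_mixture map by bisection (the map is
    strictly increasing).  Concentrations driving the effect above the
    least attainable component maximum are truncated to that maximum.
    Single-component designs reduce exactly to the component curve.
    """
    _check_components(design, curves, "fitted curve")
    c = np.atleast_1d(np.asarray(total_concentration, dtype=float))
    if np.any(c < 0):
        raise ValueError("total concentration must be non-negative")
    if len(design.compounds) == 1:
        out = np.zeros_like(c)
        pos = c > 0
        out[pos] = curves[design.compounds[0]].predict(c[pos])
        return out if np.ndim(total_concentration) else float(out[0])

    p = design.mole_fractions
    thetas = [curves[comp] for comp in design.compounds]
    emax = _attainable_max(design, curves)

    def ca_total(x):
        with np.errstate(over="ignore", divide="ignore"):
            denom = np.zeros_like(x)
            for frac, curve in zip(p, thetas):
                denom += frac / curve.invert(x)
            return 1.0 / denom

    lo = np.full(c.shape, 1e-12)
    hi = np.full(c.shape, emax * (1 - 1e-12))
    out = np.zeros_like(c)
    pos = c > 0
    if pos.any():
        cp = c[pos]
        lo_p, hi_p = lo[pos], hi[pos]
        # clamp above the attainable range
        top = ca_total(hi_p)
        clamped = cp >= top
        for _ in range(n_iter):
            mid = 0.5 * (lo_p + hi_p)
            too_low = ca_total(mid) < cp
            lo_p = np.where(too_low, mid, lo_p)
            hi_p = np.where(too_low, hi_p, mid)
        sol = 0.5 * (lo_p + hi_p)
        sol[clamped] = emax * (1 - 1e-12)
        res = out[pos]
        res[:] = sol
        out[pos] = res
    return out if np.ndim(total_concentration) else float(out[0])


# --------------------------------------------------------------------------
# independent action


def ia_effect(design: MixtureDesign, curves: Mapping, c_mixture) -> np.ndarray:
    """IA-predicted effect: E = 1 - prod_i (1 - E_i(p_i * c))."""
    _check_components(design, curves, "fitted curve")
    c = np.atleast_1d(np.asarray(c_mixture, dtype=float))
    if np.any(c < 0):
        raise ValueError("total concentration must be non-negative")
    surv = np.ones_like(c)
    pos = c > 0
    for frac, compound in zip(design.mole_fractions, design.compounds):
        e = np.zeros_like(c)
        e[pos] = curves[compound].predict(frac * c[pos])
        surv *= 1.0 - np.clip(e, 0.0, 1.0)
    out = 1.0 - surv
    return out if np.ndim(c_mixture) else float(out[0])


def ia_curve(design: MixtureDesign, curves: Mapping, concentration_grid) -> MixtureCurve:
    """IA-predicted mixture curve over a total-concentration grid."""
    grid = np.asarray(concentration_grid, dtype=float)
    return MixtureCurve(model="IA", total_concentration=grid,
                        effects=np.asarray(ia_effect(design, curves, grid)),
                        design=design)
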