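"""Sigmoidal concentration-response modelling for luminescence inhibition assays.

The unit of analysis is the per-experiment mean of control-normalized
inhibition values: raw luminescence readings (one per embryoid body) are
normalized to the mean of the control wells *within the same experiment*,

    effect = 1 - luminescence / mean(control luminescence),

and the per-(experiment, concentration) means of these effects are the data
points entering the nonlinear regression.  Fitting is done on log10
concentration with unweighted least squares; controls anchor the
normalization (effect 0 by construction) and are excluded from the
regression design because c = 0 has no log-concentration.

Four sigmoidal model families are supported, each of the form

    E(c) = theta3 * G(theta1 + theta2 * log10 c),

with G the logistic, normal or Gompertz (Weibull) CDF and theta3 a maximum
effect fixed at 1 except for the generalized logit.  A best-fit suite fits
all families and selects the one with the smallest small-sample-corrected
AIC (AICc).  Fitted curves support closed-form inversion, which yields ICx
values and the benchmark concentration (BMC) at a chosen benchmark response
(BMR, default 10% inhibition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr, ndtri
from scipy.special import logit as _logit_link

__all__ = [
    "MissingControlError",
    "UnattainableEffectError",
    "normalize_to_controls",
    "ModelFamily",
    "get_family",
    "FAMILY_ORDER",
    "SigmoidCurve",
    "BenchmarkEstimate",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_curve",
    "select_best_fit",
    "fit_best",
    "relative_potency",
]


class MissingControlError(ValueError):
    """An experiment contributed treated readings but no control readings."""


class UnattainableEffectError(ValueError):
    """Requested effect level is at or above the curve's maximum effect."""


# --------------------------------------------------------------------------
# normalization


def normalize_to_controls(
    records: pd.DataFrame, *, control_label: str = "control"
) -> pd.DataFrame:
    """Control-normalize raw luminescence and aggregate per experiment.

    Parameters
    ----------
    records : DataFrame
        Plate-format records with columns ``experiment_id``, ``treatment_id``,
        ``luminescence_rlu`` (or ``luminescence``) and ``concentration_uM``
        (or ``concentration``); ``compound``, ``mixture_id`` and
        ``enrichment_factor`` columns are carried through when present.
    control_label : str
        ``treatment_id`` value identifying control wells.

    Returns
    -------
    DataFrame
        One row per (experiment, treatment, concentration) with the mean
        normalized inhibition in column ``effect``.  Control effects average
        to exactly 0 within each experiment by construction.

    Raises
    ------
    MissingControlError
        If any experiment present in ``records`` has no control readings.
    """
    df = records.copy()
    lum_col = "luminescence_rlu" if "luminescence_rlu" in df.columns else "luminescence"
    conc_col = "concentration_uM" if "concentration_uM" in df.columns else "concentration"
    if lum_col not in df.columns:
        raise KeyError("records lack a luminescence column")
    if conc_col not in df.columns:
        raise KeyError("records lack a concentration column")

    ctrl = df[df["treatment_id"] == control_label]
    control_means = ctrl.groupby("experiment_id")[lum_col].mean()
    missing = sorted(set(df["experiment_id"]) - set(control_means.index))
    if missing:
        raise MissingControlError(
            f"experiments without control readings: {missing}"
        )

    df["effect"] = 1.0 - df[lum_col] / df["experiment_id"].map(control_means)

    keys = ["experiment_id", "treatment_id"]
    for extra in ("compound", "mixture_id"):
        if extra in df.columns:
            keys.append(extra)
    keys.append(conc_col)
    if "enrichment_factor" in df.columns:
        keys.append("enrichment_factor")
    out = df.groupby(keys, as_index=False, dropna=False)["effect"].mean()
    return out.rename(columns={conc_col: "concentration"})


# --------------------------------------------------------------------------
# model families


class ModelFamily:
    """A sigmoidal family E = emax * G(theta1 + theta2*log10 c).

    Subclasses supply the CDF ``G`` and its inverse (the link).  ``theta``
    is ``(theta1, theta2)`` for two-parameter families and
    ``(theta1, theta2, theta3)`` when the family estimates a maximum effect.
    """

    name: str = ""
    n_params: int = 2
    has_max = False

    # link/CDF/density on the standardized scale
    def _cdf(self, z):
        raise NotImplementedError

    def _link(self, p):
        raise NotImplementedError

    def _pdf(self, z):
        raise NotImplementedError

    def max_effect(self, theta) -> float:
        return float(theta[2]) if self.has_max else 1.0

    def predict_logc(self, theta, logc):
        z = theta[0] + theta[1] * np.asarray(logc, dtype=float)
        return self.max_effect(theta) * self._cdf(z)

    def jacobian_logc(self, theta, logc):
        """Analytic Jacobian of the predicted effect w.r.t. theta."""
        x = np.asarray(logc, dtype=float)
        z = theta[0] + theta[1] * x
        g = self.max_effect(theta) * self._pdf(z)
        cols = [g, g * x]
        if self.has_max:
            cols.append(self._cdf(z))
        return np.column_stack(cols)

    def inverse_logc(self, theta, effect):
        """log10 concentration producing ``effect``; effect strictly inside (0, emax)."""
        p = np.asarray(effect, dtype=float) / self.max_effect(theta)
        return (self._link(p) - theta[0]) / theta[1]

    # batch variants over a (B, p) parameter matrix, used by the bootstrap
    # and Monte-Carlo machinery; subclasses with non-standard third
    # parameters override these alongside the scalar methods

    def batch_predict(self, TH, logx):
        z = TH[:, 0:1] + TH[:, 1:2] * logx
        emax = TH[:, 2:3] if self.has_max else 1.0
        return emax * self._cdf(z)

    def batch_jacobian(self, TH, logx):
        z = TH[:, 0:1] + TH[:, 1:2] * logx
        emax = TH[:, 2:3] if self.has_max else 1.0
        g = emax * self._pdf(z)
        cols = [g, g * logx]
        if self.has_max:
            cols.append(self._cdf(z))
        return np.stack(cols, axis=-1)

    def batch_inverse_logc(self, TH, effect):
        emax = TH[:, 2:3] if self.has_max else 1.0
        return (self._link(effect / emax) - TH[:, 0:1]) / TH[:, 1:2]

    def batch_max_effect(self, TH):
        return TH[:, 2] if self.has_max else np.ones(TH.shape[0])

    @property
    def bounds(self):
        lo = [-60.0, 1e-8]
        hi = [60.0, 60.0]
        if self.has_max:
            lo.append(0.2)
            hi.append(1.0)
        return np.array(lo), np.array(hi)

    def default_starts(self, logc, effect):
        """Deterministic multi-start grid plus a linearized-link start."""
        logc = np.asarray(logc, dtype=float)
        effect = np.asarray(effect, dtype=float)
        quantiles = np.quantile(logc, [0.25, 0.5, 0.75])
        starts = []
        for slope in (0.5, 1.0, 2.0, 4.0, 8.0):
            for mid in quantiles:
                starts.append([-slope * mid, slope])
        # linear regression of link(effect) on logc where usable
        inside = (effect > 0.005) & (effect < 0.995)
        if inside.sum() >= 2:
            z = self._link(np.clip(effect[inside], 0.005, 0.995))
            slope, intercept = np.polyfit(logc[inside], z, 1)
            if slope > 1e-8:
                starts.append([intercept, slope])
        if self.has_max:
            starts = [s + [0.95] for s in starts]
        return [np.asarray(s, dtype=float) for s in starts]


class LogitFamily(ModelFamily):
    name = "logit"

    def _cdf(self, z):
        return expit(z)

    def _link(self, p):
        return _logit_link(p)

    def _pdf(self, z):
        e = expit(z)
        return e * (1.0 - e)


class ProbitFamily(ModelFamily):
    name = "probit"

    def _cdf(self, z):
        return ndtr(z)

    def _link(self, p):
        return ndtri(p)

    def _pdf(self, z):
        return np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)


class WeibullFamily(ModelFamily):
    """Gompertz/extreme-value CDF, E = emax*(1 - exp(-exp(z)))."""

    name = "weibull"

    def _cdf(self, z):
        return -np.expm1(-np.exp(z))

    def _link(self, p):
        return np.log(-np.log1p(-np.asarray(p, dtype=float)))

    def _pdf(self, z):
        return np.exp(z - np.exp(z))


class GeneralizedLogitFamily(LogitFamily):
    """Logistic CDF with an estimated maximum effect theta3 in (0.2, 1]."""

    name = "generalized-logit"
    n_params = 3
    has_max = True


class RichardsFamily(ModelFamily):
    """Asymmetric logistic (Richards), E = expit(z)^gamma, gamma = theta3.

    The exponent lets the curve rise with different shapes below and above
    the midpoint, which matters when a single regression has to track a
    composite response (e.g. an observed mixture whose true shape is a
    concentration-addition blend of several sigmoids).
    """

    name = "richards"
    n_params = 3
    has_max = False  # theta3 is a shape exponent, the maximum stays 1

    def max_effect(self, theta) -> float:
        return 1.0

    def predict_logc(self, theta, logc):
        z = theta[0] + theta[1] * np.asarray(logc, dtype=float)
        return expit(z) ** theta[2]

    def inverse_logc(self, theta, effect):
        p = np.asarray(effect, dtype=float) ** (1.0 / theta[2])
        return (_logit_link(p) - theta[0]) / theta[1]

    def jacobian_logc(self, theta, logc):
        x = np.asarray(logc, dtype=float)
        z = theta[0] + theta[1] * x
        u = expit(z)
        e = u ** theta[2]
        dz = theta[2] * e * (1.0 - u)
        return np.column_stack([dz, dz * x, e * np.log(np.maximum(u, 1e-300))])

    @property
    def bounds(self):
        return (np.array([-60.0, 1e-8, 0.05]), np.array([60.0, 60.0, 20.0]))

    def default_starts(self, logc, effect):
        logc = np.asarray(logc, dtype=float)
        effect = np.asarray(effect, dtype=float)
        quantiles = np.quantile(logc, [0.25, 0.5, 0.75])
        starts = [[-slope * mid, slope, gamma]
                  for slope in (0.5, 1.0, 2.0, 4.0, 8.0)
                  for mid in quantiles[1:2]
                  for gamma in (0.5, 1.0, 2.0)]
        inside = (effect > 0.005) & (effect < 0.995)
        if inside.sum() >= 2:
            z = _logit_link(np.clip(effect[inside], 0.005, 0.995))
            slope, intercept = np.polyfit(logc[inside], z, 1)
            if slope > 1e-8:
                for gamma in (0.5, 1.0, 2.0):
                    starts.append([intercept, slope, gamma])
        return [np.asarray(s, dtype=float) for s in starts]

    def batch_predict(self, TH, logx):
        z = TH[:, 0:1] + TH[:, 1:2] * logx
        return expit(z) ** TH[:, 2:3]

    def batch_jacobian(self, TH, logx):
        z = TH[:, 0:1] + TH[:, 1:2] * logx
        u = expit(z)
        e = u ** TH[:, 2:3]
        dz = TH[:, 2:3] * e * (1.0 - u)
        return np.stack([dz, dz * logx, e * np.log(np.maximum(u, 1e-300))],
                        axis=-1)

    def batch_inverse_logc(self, TH, effect):
        p = np.asarray(effect, dtype=float) ** (1.0 / TH[:, 2:3])
        return (_logit_link(p) - TH[:, 0:1]) / TH[:, 1:2]

    def batch_max_effect(self, TH):
        return np.ones(TH.shape[0])


_FAMILIES = {
    f.name: f
    for f in (LogitFamily(), ProbitFamily(), WeibullFamily(),
              GeneralizedLogitFamily(), RichardsFamily())
}
_FAMILIES["genlogit"] = _FAMILIES["generalized-logit"]

#: tie-break order for model selection
FAMILY_ORDER = ("logit", "probit", "weibull", "generalized-logit", "richards")


def get_family(family) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown model family {family!r}; choose from {FAMILY_ORDER}"
        ) from None


# --------------------------------------------------------------------------
# curves


@dataclass(frozen=True)
class SigmoidCurve:
    """A concrete sigmoidal concentration-response curve (family + theta).

    Concentrations are in µM (or any single consistent unit such as a
    mixture enrichment factor); evaluation is on log10 concentration.
    """

    family: str
    theta: tuple

    @property
    def _fam(self) -> ModelFamily:
        return get_family(self.family)

    @property
    def max_effect(self) -> float:
        return self._fam.max_effect(self.theta)

    def predict(self, concentration):
        """Effect at positive concentration(s)."""
        c = np.asarray(concentration, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be positive")
        return self._fam.predict_logc(self.theta, np.log10(c))

    def invert(self, effect):
        """Concentration producing ``effect`` (closed form)."""
        e = np.asarray(effect, dtype=float)
        if np.any(e <= 0) or np.any(e >= self.max_effect):
            raise UnattainableEffectError(
                f"effect level unattainable: must lie strictly in (0, {self.max_effect})"
            )
        out = 10.0 ** self._fam.inverse_logc(self.theta, e)
        return float(out) if np.isscalar(effect) or np.ndim(effect) == 0 else out

    icx = invert

    def to_dict(self) -> dict:
        return {"family": self.family, "theta": list(map(float, self.theta))}

    @classmethod
    def from_dict(cls, d) -> "SigmoidCurve":
        return cls(family=d["family"], theta=tuple(d["theta"]))


@dataclass(frozen=True)
class BenchmarkEstimate:
    """Benchmark concentration at a given benchmark response level."""

    bmr: float
    bmc: float
    extrapolated: bool


# --------------------------------------------------------------------------
# model / results


class DoseResponseModel:
    """Nonlinear regression of inhibition effect on log10 concentration.

    Parameters
    ----------
    concentration : array-like, positive
        Concentrations (µM) of the per-experiment mean effect values.
        Controls (c = 0) must not be included; they anchor the normalization.
    effect : array-like
        Normalized inhibition values (0 = control level, 1 = full inhibition;
        values slightly outside [0, 1] from noise are allowed).
    family : str or ModelFamily
        One of ``logit``, ``probit``, ``weibull``, ``generalized-logit``.
    """

    def __init__(self, concentration, effect, family="logit", groups=None):
        conc = np.asarray(concentration, dtype=float)
        eff = np.asarray(effect, dtype=float)
        if conc.shape != eff.shape or conc.ndim != 1:
            raise ValueError("concentration and effect must be 1-D and congruent")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (controls excluded)")
        if not np.all(np.isfinite(eff)):
            raise ValueError("effects must be finite")
        if np.unique(conc).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        self.concentration = conc
        self.logc = np.log10(conc)
        self.effect = eff
        self.family = get_family(family)
        # experiment labels per point; lets the bootstrap respect the
        # shared within-experiment error the control normalization induces
        self.groups = None if groups is None else np.asarray(groups)
        if self.groups is not None and self.groups.shape != conc.shape:
            raise ValueError("groups must be congruent with concentration")

    @classmethod
    def from_effects(cls, effects: pd.DataFrame, family="logit") -> "DoseResponseModel":
        """Build from a :func:`normalize_to_controls` table (drops controls)."""
        mask = effects["concentration"] > 0
        sub = effects.loc[mask]
        groups = sub["experiment_id"] if "experiment_id" in sub.columns else None
        return cls(sub["concentration"], sub["effect"], family=family, groups=groups)

    def _residuals(self, theta):
        return self.family.predict_logc(theta, self.logc) - self.effect

    def _jacobian(self, theta):
        return self.family.jacobian_logc(theta, self.logc)

    def fit(self, starts: Iterable | None = None) -> "DoseResponseResults":
        """Multi-start bounded least squares.

        Non-convergence is reported through ``converged`` on the returned
        results object, never raised, so a failed family can simply be
        excluded from best-fit selection.
        """
        fam = self.family
        lo, hi = fam.bounds
        if starts is None:
            starts = fam.default_starts(self.logc, self.effect)
        best = None
        for th0 in starts:
            th0 = np.clip(th0, lo, hi)
            try:
                res = optimize.least_squares(
                    self._residuals, th0, jac=self._jacobian, bounds=(lo, hi),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=2000,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
        if best is None:
            return DoseResponseResults(
                model=self, family=fam.name, theta=tuple(np.clip([0.0, 1.0], lo, hi)),
                rss=math.inf, nobs=self.effect.size, converged=False,
            )
        rss, res = best
        return DoseResponseResults(
            model=self, family=fam.name, theta=tuple(map(float, res.x)),
            rss=rss, nobs=self.effect.size, converged=bool(res.status > 0),
        )


class DoseResponseResults:
    """Fit results: parameter estimates, diagnostics, inversion, BMC.

    Normally produced by :meth:`DoseResponseModel.fit`; can also be rebuilt
    from a serialized dict (``from_dict``), in which case the design points
    are absent and only curve evaluation/inversion is available.
    """

    def __init__(self, *, model=None, family, theta, rss, nobs, converged,
                 conc_range=None):
        self.model = model
        self.family = family
        self.theta = tuple(theta)
        self.rss = float(rss)
        self.nobs = int(nobs)
        self.converged = bool(converged)
        if conc_range is None and model is not None:
            conc_range = (float(model.concentration.min()),
                          float(model.concentration.max()))
        self.conc_range = conc_range
        self.curve = SigmoidCurve(family=family, theta=self.theta)

    # -- diagnostics -------------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.theta)

    @property
    def aicc(self) -> float:
        """Small-sample-corrected AIC; residual variance counts as a parameter."""
        n, k = self.nobs, self.n_params + 1
        if not self.converged or not math.isfinite(self.rss):
            return math.inf
        if n - k - 1 <= 0:
            return math.inf
        rss = max(self.rss, 1e-300)
        return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def residual_scale(self) -> float:
        """Residual standard error sqrt(RSS / (n - p)); 0 on a perfect fit."""
        dof = self.nobs - self.n_params
        if dof <= 0:
            return 0.0
        return math.sqrt(max(self.rss, 0.0) / dof)

    @property
    def max_effect(self) -> float:
        return self.curve.max_effect

    # -- curve interface ---------------------------------------------------

    def predict(self, concentration):
        return self.curve.predict(concentration)

    def invert(self, effect):
        return self.curve.invert(effect)

    def icx(self, x):
        """Concentration producing an x inhibition (x as a fraction, e.g. 0.5)."""
        return self.curve.invert(x)

    def bmc(self, bmr: float = 0.10, tested_range=None) -> BenchmarkEstimate:
        """Benchmark concentration at benchmark response ``bmr``.

        ``extrapolated`` is flagged when the BMC falls outside the tested
        concentration range (default: the fitted data's range).
        """
        value = self.curve.invert(bmr)
        rng = tested_range if tested_range is not None else self.conc_range
        extrapolated = bool(rng is not None and not (rng[0] <= value <= rng[1]))
        return BenchmarkEstimate(bmr=float(bmr), bmc=float(value),
                                 extrapolated=extrapolated)

    # -- bookkeeping -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Concentration-response fit",
            "=" * 42,
            f"family:     {self.family}",
            f"converged:  {self.converged}",
            f"nobs:       {self.nobs}",
            f"theta1 (location): {self.theta[0]: .6g}",
            f"theta2 (slope):    {self.theta[1]: .6g}",
        ]
        if len(self.theta) > 2:
            lines.append(f"theta3 (max eff.): {self.theta[2]: .6g}")
        lines += [
            f"RSS:        {self.rss: .6g}",
            f"AICc:       {self.aicc: .6g}",
        ]
        if self.converged:
            try:
                lines.append(f"BMC10:      {self.curve.invert(0.10): .6g} uM")
                lines.append(f"IC50:       {self.curve.invert(0.50): .6g} uM")
            except UnattainableEffectError:
                pass
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "theta": list(map(float, self.theta)),
            "rss": self.rss,
            "aicc": self.aicc,
            "n_points": self.nobs,
            "converged": self.converged,
            "concentration_range": list(self.conc_range) if self.conc_range else None,
        }

    @classmethod
    def from_dict(cls, d) -> "DoseResponseResults":
        return cls(
            model=None, family=d["family"], theta=tuple(d["theta"]),
            rss=d.get("rss", float("nan")), nobs=d.get("n_points", 0),
            converged=d.get("converged", True),
            conc_range=tuple(d["concentration_range"]) if d.get("concentration_range") else None,
        )


# --------------------------------------------------------------------------
# suite fitting / selection


def fit_curve(effects: pd.DataFrame, family="logit") -> DoseResponseResults:
    """Fit one family to a normalized effect table (controls excluded)."""
    return DoseResponseModel.from_effects(effects, family=family).fit()


def select_best_fit(fits: Sequence[DoseResponseResults]) -> DoseResponseResults:
    """Pick the converged fit with minimal AICc.

    Ties (AICc within 1e-9) are broken by fewer parameters, then by the
    fixed family order logit, probit, weibull, generalized-logit.
    """
    converged = [f for f in fits if f.converged and math.isfinite(f.aicc)]
    if not converged:
        raise ValueError("no converged fits to select from")
    best_aicc = min(f.aicc for f in converged)
    tied = [f for f in converged if f.aicc <= best_aicc + 1e-9]

    def order(f):
        try:
            idx = FAMILY_ORDER.index(f.family)
        except ValueError:
            idx = len(FAMILY_ORDER)
        return (f.n_params, idx)

    return min(tied, key=order)


def fit_best(effects: pd.DataFrame, families=FAMILY_ORDER):
    """Fit every family in the suite and return (best, all fits)."""
    fits = [fit_curve(effects, family=fam) for fam in families]
    return select_best_fit(fits), fits


def relative_potency(values: Mapping[str, float], reference: str) -> dict:
    """Relative potency factors value_ref / value_i (reference maps to 1).

    ``values`` are potency concentrations (BMC10 or IC50, µM): a *smaller*
    concentration means a *more* potent compound, hence the inverted ratio.
    """
    if reference not in values:
        raise KeyError(f"reference compound {reference!r} not in values")
    for k, v in values.items():
        if not (v > 0):
            raise ValueError(f"potency value for {k!r} must be positive")
    ref = values[reference]
    out = {k: ref / v for k, v in values.items()}
    out[reference] = 1.0
    return out
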