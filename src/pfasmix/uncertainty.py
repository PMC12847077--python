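"""Parametric bootstrap and Monte-Carlo 95% bands for mixture predictions.

Uncertainty in the component concentration-response fits is propagated to
the CA/IA mixture predictions in two stages:

1. *Parametric bootstrap* per component: synthetic effect data are drawn
   from the fitted model (fitted value + Gaussian residual with the
   parent's residual standard error, at the original design points) and
   refitted with the same family, giving an ensemble of resampled curves.
2. *Monte-Carlo propagation*: each MC draw samples one bootstrap member
   per component independently (matching the non-interaction assumption),
   computes the predicted mixture curve, and the pointwise 2.5th/97.5th
   percentiles over draws form the approximate 95% band.  The band's point
   estimate is the prediction from the parent fits.

Observed-mixture bands use the same parametric bootstrap applied to the
curve fitted to the observed mixture data.  When the 95% bands of observed
and predicted responses do not overlap at a grid node, the difference at
that node is considered statistically significant (interval non-overlap
rule; no additional test statistic is computed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .doseresponse import (
    FAMILY_ORDER,
    DoseResponseModel,
    DoseResponseResults,
    SigmoidCurve,
    get_family,
)
from .mixture import MixtureDesign, ca_effect_at, ia_effect

__all__ = [
    "BootstrapEnsemble",
    "PredictionBand",
    "BandComparison",
    "parametric_bootstrap",
    "ensemble_band",
    "mc_mixture_band",
    "compare_bands",
]


def _batch_refit(family, logc, Y, theta0):
    """Refit one family to a batch of bootstrap datasets at once.

    Damped Gauss-Newton (Levenberg-Marquardt) vectorized over the batch
    axis; every dataset shares the design points and is warm-started at
    the parent estimate, so a handful of iterations suffice.  Parameters
    are projected onto the family's bounds after each step.  Returns
    ``(theta, rss, converged)``; draws that fail to converge here are
    refitted with the reference optimizer by the caller.
    """
    x = np.asarray(logc, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B, n = Y.shape
    lo, hi = family.bounds
    p = lo.size
    theta = np.tile(np.asarray(theta0, dtype=float), (B, 1))
    lam = np.full(B, 1e-3)

    r = family.batch_predict(theta, x) - Y
    rss = np.einsum("bn,bn->b", r, r)
    active = np.ones(B, dtype=bool)
    for _ in range(150):
        if not active.any():
            break
        J = family.batch_jacobian(theta[active], x)
        g = np.einsum("bnp,bn->bp", J, r[active])
        H = np.einsum("bnp,bnq->bpq", J, J)
        Hd = H.copy()
        d = np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-12)
        Hd[:, np.arange(p), np.arange(p)] += lam[active, None] * d
        try:
            step = np.linalg.solve(Hd, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            break
        cand = np.clip(theta[active] + step, lo, hi)
        rc = family.batch_predict(cand, x) - Y[active]
        rss_c = np.einsum("bn,bn->b", rc, rc)
        better = rss_c <= rss[active]
        idx = np.flatnonzero(active)
        acc = idx[better]
        theta[acc] = cand[better]
        r[acc] = rc[better]
        improved = rss[acc] - rss_c[better]
        rss[acc] = rss_c[better]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 5.0, 1e7)
        done = np.zeros(B, dtype=bool)
        done[acc] = improved < 1e-12 * (1.0 + rss[acc])
        # heavily damped rejected steps: the warm start is already a
        # stationary point at working precision
        done[idx[~better]] = lam[idx[~better]] >= 1e6
        active = active & ~done
    converged = ~active
    return theta, rss, converged


def _batch_aicc(fam, rss, conv, n):
    k = fam.n_params + 1
    if n - k - 1 <= 0:
        return np.full(rss.shape, np.inf)
    return np.where(
        conv,
        n * np.log(np.maximum(rss, 1e-300) / n) + 2 * k
        + 2 * k * (k + 1) / (n - k - 1),
        np.inf)


def _residual_components(model, theta, fitted, s):
    """Split the residual variance into per-experiment and per-point parts.

    One-way method of moments on the parent residuals grouped by
    experiment; without groups (or with a single group) everything is
    per-point and the classical iid-residual bootstrap is recovered.
    Degrees of freedom lost to the curve fit are charged to the
    within-group mean square.

    Returns ``(ms_within, nu_within, ms_between, nu_between, n0,
    group_idx, n_groups)``; ``ms_between``/``group_idx`` are ``None``
    without usable groups.
    """
    n = fitted.size
    p = len(theta)
    if model.groups is None:
        return s**2, max(n - p, 1), None, 0, 0.0, None, 0
    labels, group_idx = np.unique(model.groups, return_inverse=True)
    g = labels.size
    if g < 2 or n - g - p + 1 <= 0:
        return s**2, max(n - p, 1), None, 0, 0.0, None, 0
    r = model.effect - fitted
    group_means = np.bincount(group_idx, weights=r) / np.bincount(group_idx)
    within = r - group_means[group_idx]
    nu_w = n - g - p + 1
    ms_within = float(np.sum(within**2) / nu_w)
    n0 = n / g  # balanced designs in practice
    ms_between = float(
        np.sum(np.bincount(group_idx) * (group_means - r.mean())**2) / (g - 1))
    return ms_within, nu_w, ms_between, g - 1, n0, group_idx, g


@dataclass
class BootstrapEnsemble:
    """Resampled model fits for one compound (or one observed mixture)."""

    compound: str
    parent: DoseResponseResults
    members: list
    n_boot: int
    seed: int
    n_failed: int = 0
    warning: str | None = None


@dataclass(frozen=True)
class PredictionBand:
    """Pointwise 95% limits around a predicted (or observed) response."""

    model: str  # "CA", "IA" or "observed"
    grid: np.ndarray  # total concentrations (µM) or enrichment factors
    lower: np.ndarray
    point: np.ndarray
    upper: np.ndarray
    n_truncated: int = 0

    def __post_init__(self):
        for name in ("grid", "lower", "point", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.grid.shape == self.lower.shape == self.point.shape == self.upper.shape):
            raise ValueError("band vectors must share the grid's shape")


def parametric_bootstrap(results: DoseResponseResults, n_boot: int = 1000,
                         seed: int = 0, families=None) -> BootstrapEnsemble:
    """Bootstrap a converged fit by resampling from the fitted model.

    Each member is a refit (same family) to synthetic data drawn from the
    fitted model at the original design points: fitted value plus Gaussian
    residual noise with the parent's residual standard error.  When the
    design points carry experiment labels, the residual variance is split
    into a shared per-experiment component and an independent per-point
    component (method of moments on the parent residuals) and both are
    resampled; control normalization makes effects within an experiment
    share part of their error, and ignoring that correlation makes the
    resulting bands too narrow.  Refits are warm-started at the parent
    estimate; failures fall back to the full multi-start grid and are
    counted in ``n_failed`` (a warning is attached when more than 20% of
    members fail).  With zero residual variance every member equals the
    parent.

    ``families`` switches the refit from same-family (default) to full
    best-fit re-selection: each member refits every family in ``families``
    and keeps the AICc winner, mirroring an estimation procedure that
    itself includes model selection.  Bands built from re-selecting
    ensembles carry the selection step's contribution to the sampling
    variability, which same-family refits omit.
    """
    if not results.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    model = results.model
    if model is None:
        raise ValueError("results carry no data; bootstrap needs the design points")
    rng = np.random.default_rng(seed)
    s = results.residual_scale
    compound = getattr(results, "compound", "") or ""

    # a perfect fit leaves numerically-zero residuals; treat as degenerate
    if s < 1e-10:
        members = [results.curve] * n_boot
        return BootstrapEnsemble(compound=compound, parent=results, members=members,
                                 n_boot=n_boot, seed=seed, n_failed=0)

    fitted = model.family.predict_logc(results.theta, model.logc)
    ms_w, nu_w, ms_b, nu_b, n0, group_idx, n_groups = _residual_components(
        model, results.theta, fitted, s)

    # per-family parent fits provide the warm starts for member refits
    if families is None:
        warm = {model.family.name: (model, np.asarray(results.theta, dtype=float))}
    else:
        warm = {}
        for fam in families:
            m = DoseResponseModel(model.concentration, model.effect, family=fam,
                                  groups=model.groups)
            fit = m.fit() if fam != model.family.name else results
            if fit.converged:
                warm[fam] = (m, np.asarray(fit.theta, dtype=float))
        if not warm:
            raise ValueError("no family in the suite converged on the parent data")

    # draw all bootstrap datasets up front, then refit them family by
    # family with the batched optimizer (scipy fallback per failed draw).
    # The residual variance components are not plugged in as point
    # estimates: each member draws its own scales from their sampling
    # distributions (scaled inverse chi-squared), so the bands carry the
    # uncertainty of variance estimation - with only three experiments the
    # between-experiment mean square is itself very noisy, and ignoring
    # that makes every band too narrow.
    n = fitted.size
    var_w = ms_w * nu_w / rng.chisquare(nu_w, size=n_boot)
    Y = fitted + rng.normal(size=(n_boot, n)) * np.sqrt(var_w)[:, None]
    if ms_b is not None:
        ms_b_draw = ms_b * nu_b / rng.chisquare(nu_b, size=n_boot)
        sigma_b_draw = np.sqrt(np.maximum(0.0, (ms_b_draw - var_w) / n0))
        Y = Y + (rng.normal(size=(n_boot, n_groups))
                 * sigma_b_draw[:, None])[:, group_idx]

    fam_order = sorted(
        warm, key=lambda f: (get_family(f).n_params,
                             FAMILY_ORDER.index(f) if f in FAMILY_ORDER else 99))
    thetas, convs, aiccs = {}, {}, {}
    for fam_name in fam_order:
        fam = get_family(fam_name)
        th, rss, conv = _batch_refit(fam, model.logc, Y, warm[fam_name][1])
        thetas[fam_name], convs[fam_name] = th, conv
        aiccs[fam_name] = _batch_aicc(fam, rss, conv, n)

    # scipy fallback only for draws where no family converged in batch
    orphans = np.flatnonzero(~np.logical_or.reduce(
        [convs[f] for f in fam_order]))
    for j in orphans:
        for fam_name in fam_order:
            fam = get_family(fam_name)
            boot_model = DoseResponseModel(model.concentration, Y[j], family=fam)
            refit = boot_model.fit(starts=[warm[fam_name][1]])
            if refit.converged:
                thetas[fam_name][j] = refit.theta
                convs[fam_name][j] = True
                aiccs[fam_name][j] = refit.aicc

    aicc_mat = np.vstack([aiccs[f] for f in fam_order])
    best_aicc = aicc_mat.min(axis=0)
    # ties broken by fewer parameters then family order (fam_order encodes both)
    choice = np.argmax(aicc_mat <= best_aicc + 1e-9, axis=0)

    members, n_failed = [], 0
    for j in range(n_boot):
        if not np.isfinite(best_aicc[j]):
            n_failed += 1
            continue
        fam_name = fam_order[choice[j]]
        members.append(SigmoidCurve(family=fam_name,
                                    theta=tuple(thetas[fam_name][j])))
    warning = None
    if n_failed > 0.2 * n_boot:
        warning = f"{n_failed}/{n_boot} bootstrap refits failed to converge"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    return BootstrapEnsemble(compound=compound, parent=results, members=members,
                             n_boot=n_boot, seed=seed, n_failed=n_failed,
                             warning=warning)


def ensemble_band(ensemble: BootstrapEnsemble, grid, model: str = "observed") -> PredictionBand:
    """Pointwise 95% band of a single bootstrapped curve over a grid."""
    grid = np.asarray(grid, dtype=float)
    if not ensemble.members:
        raise ValueError("ensemble has no converged members")
    values = np.vstack([m.predict(grid) for m in ensemble.members])
    lower, upper = np.percentile(values, [2.5, 97.5], axis=0)
    point = ensemble.parent.predict(grid)
    return PredictionBand(model=model, grid=grid, lower=lower, point=point,
                          upper=upper)


def _batch_inverse_logc(th, emax, groups, X):
    """log10 ICx for a batch of curves with mixed families; X is (B, G)."""
    out = np.empty_like(X)
    for fam_idx, rows in groups.items():
        fam = get_family(FAMILY_ORDER[fam_idx])
        out[rows] = fam.batch_inverse_logc(th[rows], X[rows])
    return out


def _batch_predict(th, emax, groups, logc):
    """Effects for a batch of curves with mixed families; logc is (B, G)."""
    out = np.empty_like(logc)
    for fam_idx, rows in groups.items():
        fam = get_family(FAMILY_ORDER[fam_idx])
        out[rows] = fam.batch_predict(th[rows], logc[rows])
    return out


def _ca_effect_draws(sampled, grid, n_mc):
    """CA effect at each grid node for every MC draw, by batched bisection."""
    G = grid.size
    emax_min = np.minimum.reduce([emax for _, _, emax, _ in sampled])

    def ca_total(X):
        # effects near 0 push ICx to 0 and the sum to inf; the bisection
        # only needs the resulting total to compare as "very small"
        with np.errstate(over="ignore", divide="ignore"):
            denom = np.zeros_like(X)
            for frac, th, emax, groups in sampled:
                denom += frac / 10.0 ** _batch_inverse_logc(th, emax, groups, X)
            return 1.0 / denom

    hi = np.broadcast_to((emax_min * (1 - 1e-12))[:, None], (emax_min.size, G)).copy()
    lo = np.full_like(hi, 1e-12)
    clamped = grid[None, :] >= ca_total(hi)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_low = ca_total(mid) < grid[None, :]
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    X = 0.5 * (lo + hi)
    X[clamped] = (emax_min * (1 - 1e-12))[:, None].repeat(G, axis=1)[clamped]
    return X, int(clamped.sum())


def _ia_effect_draws(sampled, grid, n_mc):
    """IA effect at each grid node for every MC draw (direct evaluation)."""
    surv = np.ones((n_mc, grid.size))
    for frac, th, emax, groups in sampled:
        logc = np.broadcast_to(np.log10(frac * grid)[None, :],
                               (n_mc, grid.size)).copy()
        e = _batch_predict(th, emax, groups, logc)
        surv *= 1.0 - np.clip(e, 0.0, 1.0)
    return 1.0 - surv


def mc_mixture_band(design: MixtureDesign, ensembles: dict, model: str,
                    grid, n_mc: int = 1000, seed: int = 0) -> PredictionBand:
    """Monte-Carlo 95% band for the CA or IA mixture prediction.

    Each of the ``n_mc`` draws samples one bootstrap member per component
    independently and evaluates the mixture model over ``grid`` (total
    concentrations, µM).  Grid nodes a sampled member cannot reach are
    truncated at its attainable maximum and counted in ``n_truncated``.
    """
    if model not in ("CA", "IA"):
        raise ValueError("model must be 'CA' or 'IA'")
    missing = [c for c in design.compounds if c not in ensembles]
    if missing:
        raise KeyError(f"missing ensemble for mixture component(s): {missing}")
    for c in design.compounds:
        if not ensembles[c].members:
            raise ValueError(f"ensemble for {c!r} has no converged members")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    # sample one member per component per draw, grouped by family so the
    # whole MC ensemble evaluates as a few vectorized operations
    sampled = []
    for frac, comp in zip(design.mole_fractions, design.compounds):
        members = ensembles[comp].members
        idx = rng.integers(len(members), size=n_mc)
        th = np.array([members[i].theta + (1.0,) * (3 - len(members[i].theta))
                       for i in idx])
        emax = np.array([members[i].max_effect for i in idx])
        fams = np.array([FAMILY_ORDER.index(members[i].family) for i in idx])
        groups = {f: np.flatnonzero(fams == f) for f in np.unique(fams)}
        sampled.append((frac, th, emax, groups))

    if model == "CA":
        draws, n_truncated = _ca_effect_draws(sampled, grid, n_mc)
    else:
        draws, n_truncated = _ia_effect_draws(sampled, grid, n_mc), 0
    lower, upper = np.percentile(draws, [2.5, 97.5], axis=0)
    parents = {c: ensembles[c].parent.curve for c in design.compounds}
    point_fn = ca_effect_at if model == "CA" else ia_effect
    point = np.atleast_1d(point_fn(design, parents, grid))
    return PredictionBand(model=model, grid=grid, lower=lower, point=point,
                          upper=upper, n_truncated=n_truncated)


@dataclass(frozen=True)
class BandComparison:
    """Non-overlap significance report on a shared grid."""

    grid: np.ndarray
    significant: np.ndarray  # boolean per node
    ranges: tuple  # contiguous (low, high) concentration ranges

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.significant))

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    def __str__(self) -> str:
        if not self.any_significant:
            return "no significant differences (95% bands overlap everywhere)"
        parts = ", ".join(f"[{lo:.4g}, {hi:.4g}]" for lo, hi in self.ranges)
        return (f"{self.n_significant}/{self.grid.size} nodes significant "
                f"(non-overlapping 95% bands) in range(s): {parts}")


def _interp_band(band: PredictionBand, grid):
    x = np.log10(band.grid)
    xq = np.log10(grid)
    lower = np.interp(xq, x, band.lower)
    upper = np.interp(xq, x, band.upper)
    return lower, upper


def compare_bands(observed: PredictionBand, predicted: PredictionBand) -> BandComparison:
    """Flag grid nodes where two 95% bands do not overlap.

    Both bands are linearly interpolated (in log10 concentration) onto the
    union of their grid nodes restricted to the overlapping concentration
    range, which makes the comparison symmetric in its arguments.
    """
    lo = max(observed.grid.min(), predicted.grid.min())
    hi = min(observed.grid.max(), predicted.grid.max())
    if not (lo <= hi):
        raise ValueError("band grids share no concentration range")
    grid = np.unique(np.concatenate([observed.grid, predicted.grid]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    o_lo, o_hi = _interp_band(observed, grid)
    p_lo, p_hi = _interp_band(predicted, grid)
    significant = (o_hi < p_lo) | (p_hi < o_lo)

    ranges = []
    start = None
    for i, flag in enumerate(significant):
        if flag and start is None:
            start = i
        if (not flag or i == len(significant) - 1) and start is not None:
            end = i if flag else i - 1
            ranges.append((float(grid[start]), float(grid[end])))
            start = None
    return BandComparison(grid=grid, significant=significant, ranges=tuple(ranges))
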