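# Methods

`pfasmix` implements the statistical core of a PluriLum-style embryotoxicity
study: concentration–response modelling of luminescence inhibition in
hiPSC-derived embryoid bodies (EBs), benchmark-concentration estimation,
fixed-ratio mixture prediction under concentration addition (CA) and
independent action (IA), bootstrap/Monte-Carlo uncertainty bands, and
protein-normalized cellular-uptake arithmetic.  This note records the model,
the defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical choices.

## Unit of analysis and normalization

Raw readings are per-EB luminescence values (relative light units).  Within
each independent experiment, readings are normalized to the mean of that
experiment's control EBs and expressed as inhibition,

    effect = 1 − luminescence / mean(control luminescence).

The mean of the normalized values per experiment is the unit of analysis:
with three experiments, eight concentrations and six EBs per treatment, a
single-compound regression sees 24 effect values.  Control effects average
to exactly zero within each experiment by construction, so controls anchor
the normalization and are excluded from the regression design (concentration
zero has no log-concentration anyway).

Experiments whose mean EB diameter on Day 0 is below 500 µm are discarded
wholesale before analysis.  The comparison is strict: exactly 500 µm passes.
Diameters are inputs; the package does no image analysis.

## Concentration–response model suite

Each candidate model has the form

    E(c) = θ₃ · G(θ₁ + θ₂·log₁₀ c)

with `G` a sigmoidal CDF.  The suite contains five families:

| family              | G                         | parameters | notes |
|---------------------|---------------------------|------------|-------|
| `logit`             | logistic                  | θ₁, θ₂     | θ₃ ≡ 1 |
| `probit`            | standard normal           | θ₁, θ₂     | θ₃ ≡ 1 |
| `weibull`           | Gompertz, 1−exp(−exp(z))  | θ₁, θ₂     | θ₃ ≡ 1 |
| `generalized-logit` | logistic                  | θ₁, θ₂, θ₃ | max effect θ₃ ∈ (0.2, 1] |
| `richards`          | expit(z)^γ                | θ₁, θ₂, γ  | asymmetric rise, max 1 |

Fitting is unweighted nonlinear least squares on log₁₀ concentration
(multi-start from a deterministic coarse grid over location and slope plus a
linearized-link start; `scipy.optimize.least_squares` with analytic
Jacobians, tolerances 1e−12).  The best fit is the converged candidate with
the smallest small-sample-corrected AIC,

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),   k = #θ + 1,

with ties (ΔAICc < 1e−9) broken by fewer parameters, then by the fixed
family order above.  AICc rather than AIC because n = 24 and the residual
variance counts as an estimated parameter.

The Richards family earns its place for composite responses: a fixed-ratio
mixture whose true curve is a CA blend of several sigmoids is not itself any
symmetric sigmoid.  Fitted to the noiseless CA curve of the equipotent
four-PFAS mixture at the tested design points, the best symmetric family
leaves RSS 3.3e−3 (pointwise bias up to ±0.02 — wider than a typical 95%
band); Richards leaves RSS 1.8e−5 (bias ≤ 0.0025).  With 24 points the AICc
penalty keeps it from being selected when a two-parameter family suffices.

ICx values invert the fitted curve in closed form (every family's link is
analytic); the benchmark concentration BMC₁₀ is the inversion at the
benchmark response BMR = 0.10 (10% inhibition), flagged as extrapolated when
it falls outside the tested concentration range.  IC₅₀ is absolute 50%
inhibition, not 50% of the fitted maximum; when θ₃ < 1 makes the two
diverge the requested level may be unattainable and is reported as an error
rather than silently rescaled.

Relative potency factors divide the reference compound's potency
concentration by each compound's (PFOA is the conventional reference;
smaller BMC ⇒ larger RPF).

## Mixture models

For a fixed-ratio design with mole fractions pᵢ (proportional to the
reference composition; enrichment factor 1 = the reference total):

* **Concentration addition**: ICx_mix = [Σᵢ pᵢ/ICxᵢ]⁻¹.  The CA curve is
  traced in effect space (invert each component per effect level, default
  grid 0.005–0.95 in 200 log-odds-spaced steps, dense near the BMR);
  evaluating CA at a *given* concentration inverts that strictly increasing
  map by vectorized bisection (50 halvings, machine-precision in effect).
  Effect levels at or above the least attainable component maximum are
  truncated with a warning; single-component designs short-circuit to the
  component curve exactly.
* **Independent action**: E(c) = 1 − Πᵢ(1 − Eᵢ(pᵢ·c)), evaluated directly.

When pᵢ ∝ ICxᵢ (the equipotent design) CA collapses to ICx_mix = Σ ICxᵢ/n;
with the four anchor BMC₁₀ values this gives 78.5/4 = 19.625 µM at 10%
inhibition — used throughout the tests as a closed-form oracle.

Designs harmonize units at ingestion (nM serum compositions → µM
internally) so that a mis-scaled mixture cannot arise silently.

## Uncertainty: parametric bootstrap and Monte-Carlo bands

Component-fit uncertainty is propagated to mixture predictions in two
stages.

**Parametric bootstrap per curve.**  Synthetic effect data are drawn from
the fitted model at the original design points and refitted.  Three details
matter, each adopted because the plain textbook version demonstrably
under-covers under this design:

1. *Grouped residuals.*  Control normalization divides every effect in an
   experiment by the same noisy control mean, so residuals within an
   experiment share a component.  Residual variance is split into
   between-experiment and within-experiment parts by one-way method of
   moments on the parent residuals (fit degrees of freedom charged to the
   within mean square), and both parts are resampled.
2. *Predictive variance draws.*  With three experiments the between mean
   square has two degrees of freedom; plugging in its point estimate
   truncates the component to zero in roughly half of realizations.  Each
   bootstrap member therefore draws its variances from scaled
   inverse-chi-squared sampling distributions instead of using plug-in
   values.
3. *Family re-selection.*  The estimator of record is best-fit selection
   over the whole suite, so each member refits every family (warm-started
   at the per-family parent fits) and keeps the AICc winner.  Same-family
   refits omit the selection step's contribution to sampling variability.

Member refits run in a batched damped Gauss–Newton (Levenberg–Marquardt)
loop vectorized over all resamples, with `scipy.optimize.least_squares` as
a per-draw fallback; the batch optimizer matches scipy warm refits to ~1e−7
relative on derived BMC₁₀ values.  Failed refits are counted, never
silently dropped (a warning attaches above 20%).  A perfect parent fit
(zero residual variance) yields an ensemble of parent copies.

**Monte-Carlo mixture bands.**  Each MC draw samples one bootstrap member
per component independently (matching the non-interaction assumption) and
evaluates the CA or IA curve over the concentration grid; the pointwise
2.5th/97.5th percentiles over draws form the approximate 95% band, and the
band's point estimate is the prediction from the parent fits.  Observed
mixture data get a band from the same parametric bootstrap applied to the
curve fitted to them.  Defaults n_boot = n_mc = 1000; the shipped studies
use 300 (see below).

**Significance rule.**  Two bands are compared by interval overlap: both
are linearly interpolated (in log concentration) onto the union of their
grids restricted to the shared range — making the comparison symmetric —
and a node is flagged when the intervals are disjoint.  No additional test
statistic is computed; contiguous flagged ranges are reported.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* three independent experiments, six EBs per treatment, controls in every
  experiment, eight log-spaced concentrations per compound — 0.1–200 µM for
  PFOA and PFHxS, 0.1–60 µM for PFOS, 0.1–40 µM for PFNA (the exact spacing
  within the published ranges is not stated; log spacing is standard
  practice for concentration series);
* component truth curves calibrated in closed form through two anchors,
  E(BMC₁₀) = 0.10 and E(IC₅₀) = 0.50, with the assay-derived values
  PFNA 10.2/16, PFOS 13.2/29, PFOA 23.7/83, PFHxS 31.4/230 µM;
* mixture truths generated by applying CA or IA exactly to the preset
  curves over an enrichment grid (default 0.01–1.5, the tested range of the
  equipotent design).

Noise has two components, applied to raw luminescence around a control
level of 10⁴ RLU: a per-experiment multiplicative log-normal scale
(`sigma_between`, default 0.10) that control normalization must remove, and
additive Gaussian EB-to-EB scatter on the normalized response
(`sigma_within`, default 0.05) truncated to keep luminescence positive.  No
published variance estimates exist for the assay, so the defaults are
plausible-scatter choices, recorded in the truth metadata of every
simulated dataset.  Zero noise makes the generator an exact forward
evaluation of the truth, and every run is bit-reproducible under its seed.

What the generator does **not** emulate: plate-position or edge effects,
heteroscedasticity over the concentration range, non-Gaussian outliers,
inter-compound correlation within an experiment, cytotoxic collapse at high
concentrations, or any uptake/differentiation kinetics.  Passing recovery
and coverage tests therefore show that the estimation machinery is
calibrated under its own assumptions at realistic scatter — not that real
assay data meet those assumptions.

## Validation studies and problem sizes

Two simulation studies validate the pipeline end to end (both in
`pfasmix.workflows`, reused by the acceptance script):

* **BMC₁₀ recovery** — 100 replications per compound of the full design at
  default noise; the median recovered BMC₁₀ stays within 15% of each
  preset's truth.
* **Band calibration** — 100 synthetic worlds with CA truth; per world the
  four components are fitted and bootstrapped (n_boot = 300), the CA band
  (n_mc = 300) is checked for covering the truth at the node where it
  crosses the BMR (total 19.625 µM), and an observed equipotent mixture
  simulated under the same truth is fitted, bootstrapped and compared with
  the band-overlap rule.  Ensemble sizes of 300 keep the two studies to a
  few minutes on one core while leaving percentile noise well below the
  acceptance margins; the library defaults remain 1000.

On seed series disjoint from the shipped tests, measured coverage at the
BMR node is ~93% and the false-significance rate ~5% of worlds.

## Numerical choices and degenerate inputs

* Slopes are bounded positive (θ₂ ≥ 1e−8): the assay's effect direction is
  inhibition increasing with concentration.  Flat data end at the bound or
  as a flagged non-convergence — never an exception mid-pipeline.
* Inversion requests outside a curve's attainable effect range raise
  `UnattainableEffectError`; CA truncation at a component maximum warns and
  counts truncated nodes in band diagnostics.
* Residual scales below 1e−10 are treated as a degenerate (noise-free)
  bootstrap.
* AICc is +∞ for non-converged fits and when n − k − 1 ≤ 0, excluding them
  from selection.
* Ties in selection are resolved deterministically (fewer parameters, then
  family order), so repeated runs agree bit-for-bit.

## Quantification conventions

Bradford calibration is an OLS line through (BSA concentration µg/mL,
absorbance); inversion flags, but does not reject, readings outside the
standard range.  Uptake normalizes LC–MS/MS concentrations (ng/mL) by
Bradford protein (µg/mL); methods-style ng/µg and results-style pg/mg are
both supported (1 ng/µg = 10⁶ pg/mg) with pg/mg the reporting default.
Relative uptake divides by the reference compound's mean (PFOA = 1).  The
cellular-fraction estimate takes every assumption (nominal concentration,
medium volume, well count, molar mass) as an explicit input and echoes them
in its output record.  qPCR fold changes use 2^−ΔΔCt against a housekeeping
gene and a control condition.  Group-difference testing (ANOVA/t-tests) is
left to standard statistics packages.

## Known limitations

* The non-overlap rule is conservative by construction and inherits the
  approximation quality of percentile bootstrap bands; it is a screening
  rule, not a calibrated hypothesis test.
* Between-experiment variance estimated from three experiments is
  intrinsically poor; the predictive draws widen bands accordingly, which
  trades some precision for calibration.
* CA curves above the least attainable component maximum are undefined and
  truncated; mixtures dominated by a partial-effect component should be
  interpreted only below that ceiling.
* All calibration claims are conditional on the generator's noise model;
  real plates with heavier-tailed or position-correlated noise will degrade
  coverage.
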