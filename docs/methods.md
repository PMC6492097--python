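# Methods

## Model and estimation

Per-study model: Cox proportional hazards with linear predictor
`basis(x)·β + c·γ`, where `basis` is a fractional-polynomial (FP)
transform of a strictly positive exposure and `c` holds confounder
columns passed through untransformed — their functional form is a
subject-matter choice made upstream, not an algorithmic one. The
permitted FP powers are the conventional eight,
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, with `x^0 ≡ log x` and repeated powers
generating log-multiplied columns; degree is capped at 2 (FP1/FP2).
No automatic rescaling of the exposure is applied before powering
(BMI-like exposures are safely positive); an optional pre-scale factor
is exposed for exposures of awkward magnitude.

The partial likelihood is maximized by Newton–Raphson with step-halving
from `β = 0`. Ties use Breslow's approximation by default — the
convention of the survival tooling lineage this workflow descends from —
with Efron's method available; the two coincide on continuous event
times. Delayed entry is supported through an optional entry-time column
(at risk when `entry < t ≤ time`). Internally the design is centered and
scaled to unit standard deviation: the partial likelihood is invariant
to centering, the back-transform of coefficients and covariance is
exact, and conditioning improves dramatically because `x` and `x²`
columns are nearly collinear on narrow exposure ranges. Convergence
requires relative log-likelihood change below 1e−9 **and** maximum score
component (standardized scale) below 1e−6 per event; the per-event
scaling matters because an absolute score bound is unattainable in
double precision once risk-set sums run over tens of thousands of
subjects. The coefficient covariance is the exposure block of the full
inverse observed information, so confounder uncertainty is propagated.

All risk-set quantities are computed with sorted reverse cumulative
sums; one likelihood/score/information evaluation is O(n log n + n p²)
time and O(n p) memory, which keeps 50 000-subject fits in the tens of
milliseconds.

## Selection of degree and powers

Functional-form selection inside single studies biases towards simple
shapes, so candidate FP specs are compared on the **sum** of maximized
partial log-likelihoods across studies. Powers: the degree-m spec with
the largest sum (ties broken to the lexicographically smallest power
tuple, for determinism); a study-specific per-row argmax is available
for the pointwise pooling route. A spec that fails to fit in any study
is excluded from common selection entirely, so sums always compare
identical study sets. Degree: a closed test comparing best-FP2 to the
no-exposure model, the linear model, and best-FP1 in that order, on
twice the summed log-likelihood difference. Because every study carries
its own coefficient vector, the reference distributions use
2I + 2, I + 2 and I + 1 degrees of freedom for I studies (power terms
counted once, coefficients per study); at I = 1 this is the familiar
4/3/2 convention. Both entry points — formal test or fixed degree on
subject-matter grounds — are exposed, and the workflow defaults to a
fixed degree of 2, appropriate when non-monotone shapes are plausible.

## Pooling

**Pointwise (metacurve).** At each grid value the study contrasts
`a_i(x)'β̂_i` (each study's own spec) with delta-method variances
`a_i(x)'S_i a_i(x)` enter a scalar meta-analysis. CE uses
inverse-variance weights; RE adds a heterogeneity variance τ²(x)
estimated independently at each grid point (DerSimonian–Laird default
for speed and closed form; REML optional) with no smoothing across x —
the construction is deliberately pointwise, and smoothing τ² is left as
an extension. At the reference the contrast is identically zero, so
estimate and SE are exactly 0 and the recorded weights are uniform by
convention. Studies with a non-positive-semidefinite `S_i` are dropped
with a logged reason (no ridge repair); weights renormalize over the
studies that remain.

**Multivariate (mvmeta).** Generalized-least-squares pooling of the
coefficient vectors with `V_i = S_i` (CE) or `V_i = S_i + Σ̂` (RE).
`Σ̂` is estimated by REML over a Cholesky parameterization (PSD by
construction, Nelder–Mead on the restricted likelihood, method-of-
moments start, explicit comparison against the zero-heterogeneity
boundary); a closed-form unweighted method-of-moments estimator is
available as a fast alternative. Negative heterogeneity is truncated at
zero (eigenvalue truncation in the matrix case). The returned weight
matrices satisfy `Σ W_i = I` to 1e−10. A single study under RE falls
back to CE with a warning.

The CE identity between the routes under proportional within-study
covariances (`S_i = λ_i S`) is exact in the implementation and used as
a cross-route test; the Gauss–Markov argument that the GLS contrast
variance cannot exceed the pointwise inverse-variance combination's
holds for any PSD `S_i` and is asserted at every grid point.

**Comparators and diagnostics.** The categorized-exposure comparator
cuts the pooled exposure at K quantiles, fits K−1 dummies plus
confounders per study (reference = the category containing `x0`), and
pools per-category either univariately or jointly; a category with no
events in a study contributes a missing cell, entering joint pooling
with inflated (1e10) variance so it carries no weight — the standard
data-augmentation device. Empirical-Bayes study curves shrink
`β̂_i` towards the pooled mean by `Σ̂(Σ̂ + S_i)^{-1}`, with the
conditional covariance `Σ̂ − Σ̂(Σ̂+S_i)^{-1}Σ̂` (valid for singular Σ̂).
The short-range linear meta-analysis restricts to an exposure window,
requires more than `min_events` events per study (default 10), and
pools per-study linear Cox slopes. Reference-level sensitivity re-pools
at several references on one shared grid and reports maximum absolute
re-anchored differences; for mvmeta these are zero by algebra, for
metacurve they are reported, not bounded.

Confidence bands are pointwise Wald with normal quantiles (default
95%); simultaneous bands are out of scope. The default evaluation grid
is 100 equally spaced points between the pooled 1st and 99th exposure
centiles, always augmented with the reference; evaluating at every
distinct data value is available for small datasets but infeasible at
consortium scale.

## Synthetic data

The generator exists so every pooling pathway is testable without any
external data; its defaults are the study conditions of the package's
verification suite.

Four stylized two-study designs: (1) shared quadratic truth with nadir
22, studies uniform on [20, 25] and [25, 30], 500 000 participants each;
(2) flat below 25, quadratic above; (3) quadratics of opposite sign
either side of 25, value-matched at the knot (continuous truths —
discontinuities would confound the robustness comparison); (4)
overlapping designs U(20, 30) with n = 25 000 and U(22, 28) with
n = 75 000 following opposing linear trends. The quadratic log-hazard
coefficient defaults to 0.02 per squared exposure unit (≈1.3 log-HR
units across 8 units of exposure — clear curvature without extreme
hazards). In design 4 the wide study falls and the narrow study rises at
0.15 log-HR per unit: an asymptotic analysis of the Cox information
under these designs shows the wide study dominates the pointwise
weights in the tails (its much larger spread of `x²` makes its
curvature coefficient far better determined) while the narrow,
larger study dominates very near the reference — this orientation is
what makes the pooled curve rise around the reference and fall in both
tails, the artefact the design exists to exhibit.

Event times are inverse-transform draws from a constant baseline hazard
scaled by `exp(f(x) + γ'c)`, administratively censored at time 1, with
the baseline rate solved numerically (Brent) so the mean event
probability hits a configurable target, default 10%. One named
`numpy.random.Generator` drives everything: same seed, same spec —
byte-identical data.

The consortium-like generator emulates the structure of a large
multi-cohort collaboration: log-normal cohort sizes (so some cohorts
contribute few events), cohort-shifted exposure means (sd 1.2) around a
BMI-like marginal (mean 26, within-cohort sd 4.2, clipped to [15, 45]),
age/sex/smoking-style confounders acting on the hazard, and per-cohort
curve coefficients drawn as the common FP truth plus noise with a known
between-cohort covariance — exactly the RE model the multivariate
pooling estimates, so the generator's Σ is a recoverable target. The
default Σ scales a base matrix with curvature sd 0.005 (25% of the true
curvature) and slope sd 0.24, correlation −0.9.

What the generator does **not** emulate: realistic joint covariate
distributions, case–control sampling, competing risks, non-proportional
hazards, or informative censoring. Passing tests therefore demonstrate
correctness of the estimation and pooling machinery under the stated
proportional-hazards data-generating processes, not performance on any
particular real consortium.

## Problem sizes in the verification suite

The test suite and the acceptance script run the two-study designs at
10% of the full study sizes (50 000 per study; ~5 000 events each) and
the covariance-recovery check at 60 cohorts of mean size 5 000 — sizes
chosen so the whole suite completes in a few minutes on one core while
leaving the qualitative comparisons (SE ordering, robustness ordering,
weight artefact) clearly resolved. At these scaled-down sizes the
pooled nadir of design 1 has a sampling sd of ≈0.3 exposure units
(delta-method and Monte-Carlo estimates agree), an order of magnitude
larger than at the full design sizes; summaries of the recovered nadir
therefore use the median over 10 seeded replicates.

## Known limitations

- Stratified baseline hazards, time-varying effects, one-stage pooled
  likelihoods, meta-regression, aggregate-data methods, splines, and
  pooling of absolute risk curves are out of scope.
- The Efron correction loops over tied event times; data where most
  event times are tied will fit slowly (Breslow does not).
- Per-grid-point τ² estimates are noisy where studies are few; no
  smoothing or shrinkage across grid points is applied.
- Multivariate REML uses a derivative-free optimizer; for the m ≤ 2
  cases it is fast and robust, but joint categorized pooling with many
  groups (m = K−1 large) can be slow.
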