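# Methods

## Model and parameterization

The package estimates a repeated-measures ANOVA written as a constrained
latent growth model.  Three observations of one outcome per subject, at
equally spaced categorical occasions, load on intercept (I), linear-slope
(LS) and quadratic-slope (QS) factors through the fixed orthonormal
polynomial contrast basis `C` (rows `(1,1,1)/√3`, `(−1,0,1)/√2`,
`(1,−2,1)/√6`); the loading matrix is `Λ = Cᵀ`.  Occasion-level residual
variances are fixed at zero and factor covariances at zero, so the
per-subject growth scores `η = C y` are an exact, invertible transform of
the data and carry the full likelihood.  A binary exposure indicator enters
as a regression of LS on `(1, g)`, giving seven parameters:
`μ_I, μ_LS, β, μ_QS, σ²_I, σ²_LS, σ²_QS`.

Two consequences of the zero-residual convention are used as internal
consistency checks: the implied observed-data covariance
`Λ diag(σ²_I, σ²_LS, σ²_QS) Λᵀ` has the factor variances as eigenvalues, and
the sampling variance of the ML intercept-mean estimator is exactly
`σ²_I / n` — so the Monte-Carlo MSE of `μ_I` at `n = 8` must approach
`593.633 / 8 ≈ 74.2` under the default population, which it does.

Occasions are treated as equally spaced levels regardless of their calendar
spacing, exactly as a repeated-measures ANOVA would.  Group coding is
0 = unexposed, 1 = exposed; `β` is exposed-minus-unexposed.

## Maximum likelihood

Because the transform is exact and the factors independent, the
multivariate-normal likelihood factorizes over the three score columns and
the ML solution is closed form: sample means for `μ_I`, `μ_QS`; OLS of the
LS scores on `(1, g)` for `(μ_LS, β)`; divide-by-`n` variance estimates.
Standard errors come from the observed information
(`√(σ̂²/n)` for the factor means, `σ̂²_LS (XᵀX)⁻¹` for the regression
block, `σ̂² √(2/n)` for variances), and all intervals use the normal
critical value 1.96 — the SEM-software convention, deliberately not a
t quantile; at `n = 8` this choice visibly affects power and is part of
what the simulation study measures.  A numerical maximizer of the
multivariate-normal likelihood built from the implied moments serves as an
independent oracle in the test suite; the two agree to ~1e−6 relative.

Divide-by-`n` variance estimators carry the finite-sample factors
`(n−1)/n` (I, QS) and `(n−2)/n` (LS residual): at `n = 8` the expected
relative biases are −12.5% and −25%, the mechanism behind the large
negative variance biases the ML simulation table shows.  Negative variance
estimates cannot occur on growth scores (they are mean squared residuals),
but the clamp-to-zero-and-flag branch is kept as a defensive contract.

## Gibbs sampler

Priors: `Normal(μ₀, σ²₀)` per structural parameter, `InverseGamma(shape,
scale)` per variance with density ∝ `x^(−shape−1) e^(−scale/x)`.  The
sampler alternates exact conjugate full-conditional updates — precision-
weighted normal draws for `μ_I` and `μ_QS`, a joint bivariate-normal draw
for `(μ_LS, β)` via the closed-form 2×2 Cholesky of the posterior
precision, and `IG(shape + n/2, scale + SS/2)` draws for the variances
with SS the current residual sum of squares (the number of contributing
terms is `n` for all three variances).  No tuning parameters exist; chains
are exactly reproducible from the seed.  Defaults follow the software
conventions of the motivating workflow: 10,000 iterations, first half
discarded, posterior median as the point estimate (posterior mean
available), central 2.5/97.5-percentile interval, significance = the 95%
interval excludes zero, and a one-tailed posterior p as the mass on the
opposite side of zero from the point estimate.

Improper variance priors (`IG(−1, 0)` flat-positive, `IG(0, 0)`) are
accepted only when the conditional shape `shape + n/2` is positive;
otherwise estimation is refused with an error naming the offending prior.

Starting values are the closed-form moment estimates (variances floored at
a small positive multiple of the data scale), so burn-in starts near the
posterior bulk; with a 50% burn-in the results are insensitive to this
choice, which the iteration-multiplying stability check in `diagnostics`
verifies.

The engine is replicate-vectorized: all datasets of a Monte-Carlo cell are
updated in lock-step as NumPy arrays, so 1000 replicates × 10,000
iterations at `n = 8` take on the order of ten seconds on one CPU.

### A note on variance point estimates at n = 8

Under flat structural priors the marginal posterior of `σ²_I` is
`IG(a₀ + (n−1)/2, b₀ + S/2)` with `S` the centered sum of squares.  With
the `IG(0.5, 0.5)` prior the *conditional* posterior mean given the fitted
mean is `(0.5 + SS/2)/3.5 ≈ SS/(n−1)`, an essentially unbiased quantity —
but the chain's *marginal* posterior median, the default point estimate,
sits lower: its expected relative bias at `n = 8` is
`E[b₀ + S/2]/median(Gamma(4,1)) / σ²_I − 1 ≈ −4.7%`.  The package reports
the honest marginal value (measured ≈ −4% across 1000 replicates) rather
than adopting a nonstandard summary rule.  Published figures produced by
commercial SEM software for the three variances under identical settings
scatter by several points around this analytic value and are mutually
inconsistent with any single conjugate summary rule, which we attribute to
implementation details of that software's sampler; reproducing them exactly
is out of scope.

## Synthetic data

The generator draws the factors exactly as the model assumes — independent
normals with the exposure shift on LS — and maps them through `Λ`.  Default
population values are the anchor ML estimates of the motivating cohort
(`μ_I = 54.090, μ_LS = −12.481, β = 10.008, μ_QS = 1.759, σ²_I = 593.633,
σ²_LS = 199.382, σ²_QS = 134.614`), so simulation cells reproduce the
published design by construction.  Group labels are deterministic —
exactly `round(n·allocation)` exposed subjects — to rule out single-group
replicates at `n = 8`; the default allocation is balanced (0.5), which at
`n = 8` implies a sampling variance of the `β` estimator of
`σ²_LS·(1/4 + 1/4) ≈ 99.7`, matching the published MSE of ≈ 100.9 (the
empirical cohort's 19% exposure rate would give ≈ 133 and is inconsistent
with that table).  Per-replicate RNG streams are spawned from the root seed
keyed by replicate index, so replicates are independent and individually
reproducible.

What the generator does *not* emulate: missing data (the design is
complete-case), non-normal factor distributions, floor/ceiling effects of
a bounded questionnaire score, covariate-dependent variances, and real-time
(unequal) occasion spacing.  Passing simulations therefore validate the
estimation machinery under the model's own assumptions, not robustness to
their violation.

The `calibrated_demo_dataset()` shipped for sensitivity demonstrations is a
single generated `n = 78` dataset (15 exposed) selected so its ML fit lands
near the anchor estimates; it is clearly a synthetic stand-in, not the
original cohort, which is not publicly deposited.

## Monte-Carlo evaluation

Per parameter and cell: relative mean bias `((θ̄−θ)/θ)·100` (adequacy
|bias| < 10%), 95% interval coverage of the generating value (adequacy band
0.90–0.98), power as the fraction of replicates whose interval excludes
zero, and MSE.  Variance parameters use the same interval-excludes-zero
power convention; for ML this Wald test has `z = √(n/2) = 2` at `n = 8`, so
variance power is identically 1, matching the published tables.  Bias is
reported as NaN when the generating value is zero.  Replicates whose fit
fails are excluded with bookkeeping (`n_reps_used`), with a warning above
5% failures.  The informative-`β` study sweeps the prior variance over
`{10¹⁰, 1000, 100, 50, 20, 10, 5, 3, 1}` at `n ∈ {8, 14, 22}`, reusing the
same datasets for every grid point so differences are attributable to the
prior.

## Diagnostics

A *spike* is a draw exceeding `k×` the chain median (default `k = 50`, a
scale-free stand-in for the visual trace-plot judgment; the published
criterion is qualitative).  Variance chains under improper or
barely-proper priors (`IG(−1,0)`, `IG(0.001, 0.001)`) have heavy inverse-
gamma tails at `n = 8` and show such excursions; under `IG(0.5, 0.5)` they
essentially vanish — the package reproduces this contrast qualitatively.
`split_psrf` computes the potential scale reduction factor on the two
halves of one retained chain (multi-chain PSRF is out of scope for the
single-chain fixed-iteration design); a constant chain is a degenerate
input and raises.  `iteration_stability` refits with multiplied run
lengths and reports the percent change of a point estimate.

## Problem sizes and numerical choices

The shipped test suite uses the full published scale where it is cheap
(1000 replicates for both reference tables; 10,000 iterations per Bayes
replicate) and reduced, documented sizes for property checks (250
replicates / 4000 iterations for the power-monotonicity sweep; 100,000
retained draws for distributional Kolmogorov–Smirnov checks at α = 0.01).
Monte-Carlo tolerances follow binomial error at the stated replicate
counts: ±0.03 on proportions at 1000 replicates, ±4 percentage points on
relative bias, ±10% on MSE.  Grid integration for the posterior oracle
uses a log-spaced variance grid with the Jacobian applied and ranges wide
enough that truncated mass is negligible.  All percentile computations use
linear interpolation (NumPy default).

## Known limitations

* Three occasions only; no free loadings, factor covariances or
  measurement error — the model is deliberately the minimal RMA mimic.
* Wald (normal) intervals for ML at `n = 8` are anti-conservative; that is
  a finding the package reproduces, not a defect it corrects.
* The Gibbs sampler's variance point estimates at very small `n` inherit
  the skew of the inverse-gamma posterior (see the note above); users who
  need unbiased variance reporting at `n ≤ 10` should report the full
  interval, not the point.
* Relative bias is undefined for zero-valued generating parameters and is
  reported as NaN in that (artificial) limit.
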