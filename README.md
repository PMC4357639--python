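# bayesrma

Small-sample estimation for a three-occasion repeated-measures design:
maximum likelihood and conjugate Bayesian inference for a repeated-measures
ANOVA re-expressed as a constrained latent growth model, plus the tooling a
methodologist needs around it — a synthetic-data generator, prior-sensitivity
grids, Monte-Carlo evaluation of bias / coverage / power / MSE, and MCMC
diagnostics.

## Who this is for

Researchers in clinical and epidemiological settings where the population of
interest is intrinsically small (the motivating case: posttraumatic stress
symptoms measured at 2 weeks, 6 and 12 months in burn survivors, comparing
mechanically ventilated with non-ventilated patients).  With `n` close to the
number of model parameters, ML inference loses power and variance estimates
are badly biased; informative priors can recover both, at the price of
sensitivity to the prior — which this package makes explicit and testable.

## The model

One outcome `y_i = (y_i1, y_i2, y_i3)` per subject is an exact linear
transform of three latent growth factors through the orthonormal polynomial
contrast matrix for three equally spaced occasions,

```
C = [ ( 1,  1,  1)/√3 ,      eta_i = C y_i = (I_i, LS_i, QS_i)
      (-1,  0,  1)/√2 ,      y_i   = Λ eta_i,   Λ = Cᵀ
      ( 1, -2,  1)/√6 ]
```

with independent factors

```
I_i  ~ N(μ_I,  σ²_I)
LS_i ~ N(μ_LS + β·g_i, σ²_LS)      g_i ∈ {0, 1}  (exposure indicator)
QS_i ~ N(μ_QS, σ²_QS)
```

Factor covariances and occasion-level residual variances are fixed at zero,
so the model has exactly seven parameters and the growth scores are a
bijective transform of the data.  `β`, the exposure difference in the linear
slope, is the parameter of interest.

Estimation is by

* **closed-form ML** on the growth scores (sample means, an OLS regression
  of `LS` on the group indicator, divide-by-`n` variances, Wald intervals), and
* a **conjugate Gibbs sampler** with `Normal(μ₀, σ²₀)` priors on the four
  structural parameters and `InverseGamma(shape, scale)` priors on the three
  variances (density ∝ `x^(−shape−1) e^(−scale/x)`), 10,000 iterations with
  the first half discarded by default.  The improper flat-positive prior
  `IG(−1, 0)` — a common software default — is accepted whenever the full
  conditional `IG(shape + n/2, scale + SS/2)` is proper.

## Worked example

```python
from bayesrma import (calibrated_demo_dataset, fit_ml, gibbs_sample,
                      default_priors, SamplerConfig, summarize_posterior)

data = calibrated_demo_dataset()          # synthetic stand-in cohort, n=78
fit = fit_ml(data)
print(fit.estimates.beta, fit.standard_errors["beta"], fit.ci_95["beta"])
# 10.244  4.120  (2.169, 18.318)   -> significant at the 5% level

priors = (default_priors()
          .with_variance_priors(0.5, 0.5)      # informative IG on variances
          .with_beta_prior(0.0, 20.0))         # weakly informative on beta
summary = summarize_posterior(
    gibbs_sample(data, priors=priors, config=SamplerConfig(seed=1)))
print(summary.point["beta"], summary.posterior_sd["beta"],
      summary.ppi_95["beta"], summary.one_tailed_p["beta"])
# 5.541  3.085  (-0.531, 11.628)  0.036
```

The ML fit of this n=78 stand-in finds a group difference of about 10 IES
contrast-score units with a Wald interval excluding zero.  Under a
skeptical `N(0, 20)` prior the posterior point estimate is pulled roughly
halfway toward zero and the 95% posterior interval now just includes it —
the prior-sensitivity behaviour the `sensitivity` module maps out
systematically over a (μ₀, σ²₀) grid.

The same machinery runs from the shell:

```
bayesrma simulate   --config design.yaml --out sims.csv
bayesrma fit-ml     --data data.csv --out ml.json
bayesrma fit-bayes  --data data.csv --config priors.yaml --out posterior.json
bayesrma mc-study   --config study.yaml --out metrics.csv
bayesrma sensitivity --data data.csv --config grid.yaml --out cells.csv
bayesrma diagnose   --draws draws.csv --out report.json
```

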