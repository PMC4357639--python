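"""Gibbs sampler: conjugacy, limits, determinism and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from bayesrma import (
    EstimationError,
    InputError,
    InverseGammaPrior,
    LongitudinalDataset,
    NormalPrior,
    PriorSpec,
    SamplerConfig,
    default_priors,
    fit_ml,
    gibbs_sample,
    summarize_posterior,
)
from bayesrma.bayes_fit import PosteriorChains
from bayesrma.growth_model import STRUCTURAL_NAMES, VARIANCE_NAMES


def test_default_priors_are_software_defaults():
    priors = default_priors()
    for name in STRUCTURAL_NAMES:
        assert priors.structural[name].mean == 0.0
        assert priors.structural[name].variance == 1e10
    for name in VARIANCE_NAMES:
        prior = priors.variances[name]
        assert (prior.shape, prior.scale) == (-1.0, 0.0)
        assert not prior.is_proper
    assert InverseGammaPrior(0.5, 0.5).is_proper
    with pytest.raises(InputError):
        NormalPrior(mean=0.0, variance=0.0)
    with pytest.raises(InputError):
        InverseGammaPrior(shape=0.5, scale=-1.0)


def test_same_seed_gives_identical_draws(small_dataset):
    cfg = SamplerConfig(n_iterations=500, seed=3)
    a = gibbs_sample(small_dataset, config=cfg)
    b = gibbs_sample(small_dataset, config=cfg)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])
    c = gibbs_sample(small_dataset, config=SamplerConfig(n_iterations=500, seed=4))
    assert not np.allclose(a.draws["beta"], c.draws["beta"])


def test_variance_conditional_matches_analytic_inverse_gamma(small_dataset, basis):
    """With the means pinned by near-degenerate priors, the variance draws are
    iid from the analytic InverseGamma(shape + n/2, scale + SS/2)."""
    scores = small_dataset.outcomes @ basis.contrast_matrix.T
    pinned_means = {"mu_I": 50.0, "mu_LS": -10.0, "beta": 8.0, "mu_QS": 2.0}
    priors = PriorSpec(
        structural={k: NormalPrior(mean=v, variance=1e-18)
                    for k, v in pinned_means.items()},
        variances={k: InverseGammaPrior(0.5, 0.5) for k in VARIANCE_NAMES},
    )
    cfg = SamplerConfig(n_iterations=40_000, seed=12)
    chains = gibbs_sample(small_dataset, basis, priors, cfg)

    n = small_dataset.n
    g = small_dataset.group
    ss_i = np.sum((scores[:, 0] - pinned_means["mu_I"]) ** 2)
    ss_ls = np.sum(
        (scores[:, 1] - pinned_means["mu_LS"] - pinned_means["beta"] * g) ** 2
    )
    for name, ss in (("var_I", ss_i), ("var_LS", ss_ls)):
        dist = stats.invgamma(0.5 + n / 2.0, scale=0.5 + ss / 2.0)
        pvalue = stats.kstest(chains.draws[name], dist.cdf).pvalue
        assert pvalue > 0.01, f"{name} conditional mismatch (p={pvalue:.4f})"


def test_mean_conditional_matches_analytic_normal(small_dataset, basis):
    """With variances pinned by a sharply concentrated inverse-gamma prior,
    mu_I draws follow the precision-weighted normal conditional."""
    v_fix = 400.0
    big = 1e8
    priors = PriorSpec(
        structural={
            "mu_I": NormalPrior(mean=40.0, variance=100.0),
            "mu_LS": NormalPrior(0.0, 1e10),
            "beta": NormalPrior(0.0, 1e10),
            "mu_QS": NormalPrior(0.0, 1e10),
        },
        variances={k: InverseGammaPrior(big, (big + 1.0) * v_fix)
                   for k in VARIANCE_NAMES},
    )
    cfg = SamplerConfig(n_iterations=40_000, seed=13)
    chains = gibbs_sample(small_dataset, basis, priors, cfg)
    scores = small_dataset.outcomes @ basis.contrast_matrix.T
    n = small_dataset.n
    prec = 1.0 / 100.0 + n / v_fix
    mean = (40.0 / 100.0 + scores[:, 0].sum() / v_fix) / prec
    pvalue = stats.kstest(
        chains.draws["mu_I"], stats.norm(mean, np.sqrt(1.0 / prec)).cdf
    ).pvalue
    assert pvalue > 0.01


def test_beta_posterior_matches_grid_integration_oracle(small_dataset, basis):
    """Posterior mean/SD of beta agree with dense 3-D grid integration over
    (mu_LS, beta, var_LS) to within 2%."""
    ls = (small_dataset.outcomes @ basis.contrast_matrix.T)[:, 1]
    g = small_dataset.group.astype(float)
    n = ls.size
    b_hat = ls[g == 1].mean() - ls[g == 0].mean()
    m_hat = ls[g == 0].mean()
    s_res = np.sum((ls - m_hat - b_hat * g) ** 2)
    spread = np.sqrt(s_res / n)
    mu_grid = np.linspace(m_hat - 10 * spread, m_hat + 10 * spread, 150)
    b_grid = np.linspace(b_hat - 14 * spread, b_hat + 14 * spread, 150)
    v_grid = np.exp(np.linspace(np.log(s_res / 60), np.log(s_res * 60), 220))
    M, B, V = np.meshgrid(mu_grid, b_grid, v_grid, indexing="ij")
    # IG(0.5, 0.5) prior on var_LS, near-flat normal priors on (mu_LS, beta)
    logp = -1.5 * np.log(V) - 0.5 / V
    logp -= (M**2 + B**2) / (2.0 * 1e10)
    resid2 = np.zeros_like(M)
    for i in range(n):
        resid2 += (ls[i] - M - B * g[i]) ** 2
    logp += -0.5 * n * np.log(V) - resid2 / (2.0 * V)
    logp += np.log(V)  # log-spaced grid jacobian
    w = np.exp(logp - logp.max())
    w /= w.sum()
    oracle_mean = float((w * B).sum())
    oracle_sd = float(np.sqrt((w * (B - oracle_mean) ** 2).sum()))

    priors = default_priors().with_variance_priors(0.5, 0.5)
    cfg = SamplerConfig(n_iterations=60_000, seed=9)
    draws = gibbs_sample(small_dataset, basis, priors, cfg).draws["beta"]
    assert np.mean(draws) == pytest.approx(oracle_mean, rel=0.02)
    assert np.std(draws) == pytest.approx(oracle_sd, rel=0.02)


def test_prior_dominance_limit(small_dataset):
    """As the beta prior variance shrinks, the posterior collapses on mu0."""
    priors = default_priors().with_variance_priors(0.5, 0.5)
    priors = priors.with_beta_prior(-5.0, 1e-6)
    cfg = SamplerConfig(n_iterations=4000, seed=21)
    summary = summarize_posterior(gibbs_sample(small_dataset, priors=priors,
                                               config=cfg))
    assert summary.point["beta"] == pytest.approx(-5.0, abs=0.01)


def test_data_dominance_limit(medium_dataset):
    """Flat priors at n=200: posterior means reproduce ML within MC error."""
    fit = fit_ml(medium_dataset)
    cfg = SamplerConfig(n_iterations=20_000, seed=22)
    chains = gibbs_sample(medium_dataset, priors=default_priors(), config=cfg)
    for name in STRUCTURAL_NAMES:
        post_mean = float(np.mean(chains.draws[name]))
        se = fit.standard_errors[name]
        assert post_mean == pytest.approx(getattr(fit.estimates, name),
                                          abs=0.1 * se), name
    for name in VARIANCE_NAMES:
        post_med = float(np.median(chains.draws[name]))
        assert post_med == pytest.approx(getattr(fit.estimates, name),
                                         rel=0.04), name


def test_improper_conditional_is_refused(basis, population):
    from bayesrma import SimulationDesign, generate_dataset

    data = generate_dataset(
        SimulationDesign(population, n=4, group_allocation=0.5, n_reps=1, seed=1), 0
    )
    priors = default_priors().with_variance_priors(-5.0, 0.0)
    with pytest.raises(EstimationError, match="var_I"):
        gibbs_sample(data, basis, priors, SamplerConfig(n_iterations=500, seed=0))


def test_single_group_data_is_refused(basis):
    data = LongitudinalDataset(
        outcomes=np.random.default_rng(1).normal(size=(6, 3)),
        group=np.ones(6, dtype=int),
    )
    with pytest.raises(EstimationError):
        gibbs_sample(data, basis)


def test_summary_of_constant_and_known_draws():
    cfg = SamplerConfig(n_iterations=1000, seed=0)
    priors = default_priors()
    const = {name: np.full(100, 3.0) for name in STRUCTURAL_NAMES}
    const.update({name: np.full(100, 2.0) for name in VARIANCE_NAMES})
    chains = PosteriorChains(draws=const, priors=priors, config=cfg)
    summary = summarize_posterior(chains)
    assert summary.point["beta"] == 3.0
    assert summary.posterior_sd["beta"] == 0.0
    assert summary.ppi_95["beta"] == (3.0, 3.0)
    assert summary.significant["beta"]

    rng = np.random.default_rng(8)
    z = rng.standard_normal(1_000_000)
    chains = PosteriorChains(
        draws={**{name: z for name in STRUCTURAL_NAMES},
               **{name: np.abs(z) + 0.1 for name in VARIANCE_NAMES}},
        priors=priors, config=cfg,
    )
    summary = summarize_posterior(chains)
    assert summary.ppi_95["beta"][0] == pytest.approx(-1.96, abs=0.01)
    assert summary.ppi_95["beta"][1] == pytest.approx(1.96, abs=0.01)
    assert summary.one_tailed_p["beta"] == pytest.approx(0.5, abs=0.01)
    assert not summary.significant["beta"]


def test_positive_variance_draws_enforced():
    cfg = SamplerConfig(n_iterations=1000, seed=0)
    bad = {name: np.ones(10) for name in STRUCTURAL_NAMES}
    bad.update({name: np.array([1.0, -1.0]) for name in VARIANCE_NAMES})
    with pytest.raises(InputError):
        PosteriorChains(draws=bad, priors=default_priors(), config=cfg)
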