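"""Closed-form ML estimation and Wald inference."""

import numpy as np
import pytest

from bayesrma import (
    EstimationError,
    InputError,
    LongitudinalDataset,
    SimulationDesign,
    fit_ml,
    generate_dataset,
    transform_to_growth_scores,
    wald_interval,
)
from bayesrma.growth_model import GrowthScores
from bayesrma.ml_fit import fit_ml_scores
from bayesrma.synthetic_data import generate_study_scores, group_vector


@pytest.mark.parametrize(
    "estimate, se, level, expected",
    [
        (0.0, 1.0, 0.95, (-1.959964, 1.959964)),
        (5.0, 0.0, 0.95, (5.0, 5.0)),
        # arithmetic on the published group-effect estimate and SE
        (10.008, 4.057, 0.95, (2.056, 17.960)),
    ],
)
def test_wald_interval_values(estimate, se, level, expected):
    lo, hi = wald_interval(estimate, se, level)
    assert lo == pytest.approx(expected[0], abs=5e-4)
    assert hi == pytest.approx(expected[1], abs=5e-4)


def test_wald_interval_rejects_bad_inputs():
    with pytest.raises(InputError):
        wald_interval(0.0, 1.0, 1.5)
    with pytest.raises(InputError):
        wald_interval(0.0, -1.0, 0.95)


def test_degenerate_profiles_recovered_exactly(basis):
    """Two repeated profiles per group: zero variances, exact means."""
    y0 = np.array([30.0, 20.0, 15.0])
    y1 = np.array([35.0, 30.0, 28.0])
    data = LongitudinalDataset(
        outcomes=np.vstack([y0, y0, y0, y1, y1, y1]),
        group=np.array([0, 0, 0, 1, 1, 1]),
    )
    fit = fit_ml(data, basis)
    eta0 = basis.contrast_matrix @ y0
    eta1 = basis.contrast_matrix @ y1
    assert fit.estimates.mu_I == pytest.approx((eta0[0] + eta1[0]) / 2, rel=1e-12)
    assert fit.estimates.mu_LS == pytest.approx(eta0[1], rel=1e-12)
    assert fit.estimates.beta == pytest.approx(eta1[1] - eta0[1], rel=1e-12)
    assert fit.estimates.var_I == pytest.approx(((eta1[0] - eta0[0]) / 2) ** 2)
    assert fit.estimates.var_LS == pytest.approx(0.0, abs=1e-18)
    assert fit.converged


def test_consistency_at_large_n(population):
    """OLS consistency: beta lands within 3 MC standard errors at n=1e5."""
    n = 100_000
    design = SimulationDesign(population, n=n, group_allocation=0.5,
                              n_reps=1, seed=99)
    fit = fit_ml(generate_dataset(design, 0))
    se_beta = np.sqrt(population.var_LS * 4.0 / n)
    assert fit.estimates.beta == pytest.approx(population.beta,
                                               abs=3.0 * se_beta)
    assert fit.estimates.var_I == pytest.approx(population.var_I, rel=0.05)


def test_variance_estimators_carry_finite_sample_bias(population):
    """Across replicates at n=8: E[var_I]/pop ~ 7/8 and E[var_LS]/pop ~ 6/8."""
    design = SimulationDesign(population, n=8, group_allocation=0.5,
                              n_reps=4000, seed=5150)
    scores, group = generate_study_scores(design)
    ratios_i, ratios_ls = [], []
    for r in range(design.n_reps):
        est = fit_ml_scores(GrowthScores(scores[r]), group).estimates
        ratios_i.append(est.var_I / population.var_I)
        ratios_ls.append(est.var_LS / population.var_LS)
    assert np.mean(ratios_i) == pytest.approx(7.0 / 8.0, abs=0.025)
    assert np.mean(ratios_ls) == pytest.approx(6.0 / 8.0, abs=0.025)


def test_group_relabeling_equivariance(small_dataset):
    fit = fit_ml(small_dataset)
    flipped = LongitudinalDataset(outcomes=small_dataset.outcomes,
                                  group=1 - small_dataset.group)
    fit_f = fit_ml(flipped)
    assert fit_f.estimates.beta == pytest.approx(-fit.estimates.beta, rel=1e-10)
    assert fit_f.estimates.mu_LS == pytest.approx(
        fit.estimates.mu_LS + fit.estimates.beta, rel=1e-10
    )
    assert fit_f.estimates.var_LS == pytest.approx(fit.estimates.var_LS,
                                                   rel=1e-10)
    assert fit_f.standard_errors["beta"] == pytest.approx(
        fit.standard_errors["beta"], rel=1e-10
    )


def test_significance_flag_matches_interval(small_dataset):
    fit = fit_ml(small_dataset)
    lo, hi = fit.ci_95["beta"]
    assert fit.significant_beta == (not (lo <= 0.0 <= hi))
    est, se = fit.estimates.beta, fit.standard_errors["beta"]
    assert (lo, hi) == pytest.approx((est - 1.959964 * se, est + 1.959964 * se),
                                     abs=1e-6)


def test_error_conditions(basis):
    tiny = LongitudinalDataset(outcomes=np.ones((2, 3)), group=np.array([0, 1]))
    with pytest.raises(InputError):
        fit_ml(tiny, basis)
    single_group = LongitudinalDataset(outcomes=np.random.default_rng(0)
                                       .normal(size=(5, 3)),
                                       group=np.zeros(5, dtype=int))
    with pytest.raises(EstimationError):
        fit_ml(single_group, basis)
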