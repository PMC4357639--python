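"""Maximum-likelihood estimation of the growth model.

Because the contrast transform is exact and the factors are independent,
the multivariate-normal likelihood factorizes over the three growth scores
and the ML solution is closed form: sample means for mu_I and mu_QS, an
ordinary least-squares regression of the LS scores on the group indicator
for (mu_LS, beta), and ML (divide-by-n) variance estimates.  Standard
errors come from the observed information; Wald intervals use the normal
critical value, the convention of SEM software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import EstimationError, InputError
from .growth_model import (
    ContrastBasis,
    GrowthScores,
    LongitudinalDataset,
    ParameterSet,
    STRUCTURAL_NAMES,
    VARIANCE_NAMES,
    build_contrast_basis,
    transform_to_growth_scores,
)


def wald_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-theory interval ``estimate +/- z * se``."""
    if not 0.0 < level < 1.0:
        raise InputError("confidence level must lie in (0, 1)")
    if se < 0.0:
        raise InputError("standard error must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(estimate - z * se), float(estimate + z * se)


@dataclass(frozen=True)
class MlFitResult:
    """Closed-form ML fit with Wald inference.

    ``standard_errors`` / ``ci_95`` cover the four structural parameters;
    ``variance_standard_errors`` are the large-sample observed-information
    SEs ``sqrt(2/n) * var_hat`` used for Wald inference on variances.
    """

    estimates: ParameterSet
    standard_errors: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    variance_standard_errors: dict[str, float]
    significant_beta: bool
    truncated_variances: tuple[str, ...]
    converged: bool = True


def _ml_variance(values: np.ndarray, fitted: np.ndarray) -> float:
    return float(np.mean((values - fitted) ** 2))


def fit_ml(
    data: LongitudinalDataset, basis: ContrastBasis | None = None
) -> MlFitResult:
    """Fit the model by maximum likelihood on the growth scores."""
    if data.n < 3:
        raise InputError("ML fit requires at least 3 subjects")
    if not data.both_groups_present:
        raise EstimationError(
            "both exposure groups must be present to estimate beta"
        )
    if basis is None:
        basis = build_contrast_basis()
    scores = transform_to_growth_scores(data, basis).scores
    return fit_ml_scores(GrowthScores(scores), data.group)


def fit_ml_scores(scores: GrowthScores, group: np.ndarray) -> MlFitResult:
    """ML fit directly from growth scores and group labels."""
    s = scores.scores
    g = np.asarray(group, dtype=float)
    n = s.shape[0]
    n1 = g.sum()
    if n1 <= 0 or n1 >= n:
        raise EstimationError(
            "both exposure groups must be present to estimate beta"
        )

    i_scores, ls_scores, qs_scores = s[:, 0], s[:, 1], s[:, 2]

    mu_i = float(np.mean(i_scores))
    mu_qs = float(np.mean(qs_scores))
    # OLS of LS on (1, group); the ML solution for the mean structure
    mean_ls0 = float(np.mean(ls_scores[g == 0]))
    mean_ls1 = float(np.mean(ls_scores[g == 1]))
    mu_ls, beta = mean_ls0, mean_ls1 - mean_ls0

    var_i = _ml_variance(i_scores, mu_i)
    var_qs = _ml_variance(qs_scores, mu_qs)
    var_ls = _ml_variance(ls_scores, mu_ls + beta * g)

    truncated = []
    clipped = {}
    for name, value in (("var_I", var_i), ("var_LS", var_ls), ("var_QS", var_qs)):
        if value < 0.0:  # defensive: sums of squares cannot go negative
            truncated.append(name)
            value = 0.0
        clipped[name] = value

    estimates = ParameterSet(
        mu_I=mu_i, mu_LS=mu_ls, beta=beta, mu_QS=mu_qs,
        var_I=clipped["var_I"], var_LS=clipped["var_LS"],
        var_QS=clipped["var_QS"],
    )

    # observed-information SEs; (X'X)^{-1} for X = (1, group)
    n0 = n - n1
    xtx_inv_diag = np.array([1.0 / n0, 1.0 / n0 + 1.0 / n1])
    ses = {
        "mu_I": float(np.sqrt(clipped["var_I"] / n)),
        "mu_LS": float(np.sqrt(clipped["var_LS"] * xtx_inv_diag[0])),
        "beta": float(np.sqrt(clipped["var_LS"] * xtx_inv_diag[1])),
        "mu_QS": float(np.sqrt(clipped["var_QS"] / n)),
    }
    ci = {
        name: wald_interval(getattr(estimates, name), ses[name])
        for name in STRUCTURAL_NAMES
    }
    var_ses = {
        name: float(clipped[name] * np.sqrt(2.0 / n)) for name in VARIANCE_NAMES
    }
    lo, hi = ci["beta"]
    return MlFitResult(
        estimates=estimates,
        standard_errors=ses,
        ci_95=ci,
        variance_standard_errors=var_ses,
        significant_beta=not (lo <= 0.0 <= hi),
        truncated_variances=tuple(truncated),
    )
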