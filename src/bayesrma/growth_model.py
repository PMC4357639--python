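"""Repeated-measures ANOVA expressed as a constrained latent growth model.

A single outcome is observed at three equally spaced occasions.  The three
observed scores per subject are an exact linear transform of three latent
growth factors -- intercept (I), linear slope (LS), and quadratic slope (QS)
-- through a fixed orthonormal polynomial contrast basis.  Factor covariances
are fixed to zero and the occasion-level residual variances are fixed to
zero, so the factors carry all variance and the per-subject growth scores
``eta = C @ y`` are a deterministic, invertible transform of the data.

A binary exposure indicator shifts the linear-slope mean by a coefficient
``beta``, the parameter of main scientific interest (e.g., mechanically
ventilated vs. not in a burn-survivor cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

#: canonical parameter ordering used throughout the package
PARAM_NAMES = ("mu_I", "mu_LS", "beta", "mu_QS", "var_I", "var_LS", "var_QS")
STRUCTURAL_NAMES = ("mu_I", "mu_LS", "beta", "mu_QS")
VARIANCE_NAMES = ("var_I", "var_LS", "var_QS")

#: maps each variance to the factor whose dispersion it measures
VARIANCE_OF = {"var_I": "I", "var_LS": "LS", "var_QS": "QS"}


@dataclass(frozen=True)
class ContrastBasis:
    """Orthonormal polynomial contrast basis for three occasions.

    ``contrast_matrix`` C has rows (intercept, linear, quadratic) contrasts;
    ``loading_matrix`` Lambda holds the factor loadings of the observed
    occasions on (I, LS, QS).  Because C is orthonormal, Lambda = C.T and
    C @ Lambda is the identity.
    """

    contrast_matrix: np.ndarray
    loading_matrix: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.contrast_matrix, dtype=float)
        lam = np.asarray(self.loading_matrix, dtype=float)
        if c.shape != (3, 3) or lam.shape != (3, 3):
            raise InputError("contrast and loading matrices must be 3x3")
        if not np.allclose(c @ lam, np.eye(3), atol=1e-12):
            raise InputError("loading matrix must invert the contrast matrix")
        object.__setattr__(self, "contrast_matrix", c)
        object.__setattr__(self, "loading_matrix", lam)


def build_contrast_basis() -> ContrastBasis:
    """Return the orthonormal polynomial contrasts for 3 equally spaced occasions.

    Rows: intercept (1,1,1)/sqrt(3); linear (-1,0,1)/sqrt(2); quadratic
    (1,-2,1)/sqrt(6) -- the default transformation a repeated-measures ANOVA
    applies to three within-subject levels.
    """
    c = np.array(
        [
            [1.0, 1.0, 1.0] / np.sqrt(3.0),
            [-1.0, 0.0, 1.0] / np.sqrt(2.0),
            [1.0, -2.0, 1.0] / np.sqrt(6.0),
        ]
    )
    return ContrastBasis(contrast_matrix=c, loading_matrix=c.T.copy())


@dataclass(frozen=True)
class ParameterSet:
    """The seven model parameters.

    ``mu_I``, ``mu_LS``, ``mu_QS`` are the factor means (``mu_LS`` for the
    unexposed group), ``beta`` the exposed-minus-unexposed difference in the
    linear-slope mean, and ``var_*`` the factor variances (LS: residual
    variance after the group regression).  All on the contrast-score scale
    of the outcome.
    """

    mu_I: float
    mu_LS: float
    beta: float
    mu_QS: float
    var_I: float
    var_LS: float
    var_QS: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise InputError(f"parameter {name} must be finite")
        for name in VARIANCE_NAMES:
            if getattr(self, name) < 0.0:
                raise InputError(f"variance {name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParameterSet":
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise InputError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise InputError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in values.items()})


@dataclass(frozen=True)
class LongitudinalDataset:
    """n subjects x 3 occasions of one outcome plus a 0/1 exposure indicator.

    Complete cases only: any non-finite outcome entry is rejected.
    """

    outcomes: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes, dtype=float)
        g = np.asarray(self.group)
        if y.ndim != 2 or y.shape[1] != 3:
            raise InputError("outcomes must be an n x 3 matrix")
        if not np.all(np.isfinite(y)):
            raise InputError("outcomes contain missing or non-finite values")
        if g.shape != (y.shape[0],):
            raise InputError("group must be a length-n vector")
        g_int = np.asarray(g, dtype=float)
        if not np.all(np.isin(g_int, (0.0, 1.0))):
            raise InputError("group must contain only 0 and 1")
        object.__setattr__(self, "outcomes", y)
        object.__setattr__(self, "group", g_int.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.outcomes.shape[0])

    @property
    def n_exposed(self) -> int:
        return int(self.group.sum())

    @property
    def both_groups_present(self) -> bool:
        return 0 < self.n_exposed < self.n


@dataclass(frozen=True)
class GrowthScores:
    """Per-subject (I, LS, QS) contrast scores, rows ``eta_i = C @ y_i``."""

    scores: np.ndarray = field()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise InputError("scores must be an n x 3 matrix")
        object.__setattr__(self, "scores", s)


def transform_to_growth_scores(
    data: LongitudinalDataset, basis: ContrastBasis
) -> GrowthScores:
    """Map observed occasion vectors to (I, LS, QS) growth scores."""
    return GrowthScores(scores=data.outcomes @ basis.contrast_matrix.T)


def reconstruct_outcomes(scores: GrowthScores, basis: ContrastBasis) -> np.ndarray:
    """Invert :func:`transform_to_growth_scores` (exact; loadings = C.T)."""
    return scores.scores @ basis.loading_matrix.T


def implied_moments(
    params: ParameterSet, basis: ContrastBasis, group_value: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-data mean vector and covariance for one exposure group.

    mean = Lambda @ (mu_I, mu_LS + beta * g, mu_QS);
    cov  = Lambda @ diag(var_I, var_LS, var_QS) @ Lambda.T
    (factor covariances and occasion residual variances fixed at zero).
    """
    if group_value not in (0, 1):
        raise InputError("group_value must be 0 or 1")
    lam = basis.loading_matrix
    factor_mean = np.array(
        [params.mu_I, params.mu_LS + params.beta * group_value, params.mu_QS]
    )
    factor_cov = np.diag([params.var_I, params.var_LS, params.var_QS])
    return lam @ factor_mean, lam @ factor_cov @ lam.T
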