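"""Synthetic data generation for the simulation studies.

The generator draws independent normal growth factors per subject --
I ~ N(mu_I, var_I), LS ~ N(mu_LS + beta*group, var_LS), QS ~ N(mu_QS,
var_QS) -- and maps them through the fixed loading matrix, exactly the
process the estimators assume.  It stands in for the original (non-public)
burn-survivor IES data: population values default to the maximum-likelihood
estimates that anchored the published simulation design.

Group labels are assigned deterministically (exactly ``round(n*allocation)``
exposed subjects, placed last) rather than by Bernoulli draws, so that no
replicate degenerates to a single group even at n = 8.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InputError
from .growth_model import (
    ContrastBasis,
    LongitudinalDataset,
    ParameterSet,
    build_contrast_basis,
)


def default_population() -> ParameterSet:
    """Population values used throughout the simulation studies.

    These are the ML point estimates from the motivating three-wave
    posttraumatic-stress dataset (IES outcome; exposed group = mechanically
    ventilated), on the contrast-score scale.
    """
    return ParameterSet(
        mu_I=54.0900,
        mu_LS=-12.4810,
        beta=10.0080,
        mu_QS=1.7590,
        var_I=593.6330,
        var_LS=199.3820,
        var_QS=134.6140,
    )


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of a Monte-Carlo design.

    ``group_allocation`` is the proportion of subjects assigned group = 1;
    the default 0.5 gives balanced groups.  ``seed`` is the root seed from
    which independent per-replicate streams are spawned.
    """

    population: ParameterSet
    n: int = 8
    group_allocation: float = 0.5
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError("design requires n >= 2")
        if not 0.0 < self.group_allocation < 1.0:
            raise InputError("group_allocation must lie strictly in (0, 1)")
        if self.n_reps < 1:
            raise InputError("n_reps must be at least 1")
        n1 = int(round(self.n * self.group_allocation))
        if n1 < 1 or n1 > self.n - 1:
            raise InputError(
                "group allocation leaves a group empty at this sample size"
            )

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=int(seed))


def group_vector(n: int, allocation: float) -> np.ndarray:
    """Deterministic 0/1 labels: round(n*allocation) exposed subjects, last."""
    n1 = int(round(n * allocation))
    if n1 < 1 or n1 > n - 1:
        raise InputError("allocation leaves a group empty")
    g = np.zeros(n, dtype=np.int64)
    g[n - n1 :] = 1
    return g


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate of one design."""
    if replicate_index < 0:
        raise InputError("replicate_index must be non-negative")
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(int(replicate_index),))
    )


def generate_factors(
    design: SimulationDesign, replicate_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the n x 3 latent factor matrix (I, LS, QS) and the group vector."""
    rng = _replicate_rng(design.seed, replicate_index)
    pop = design.population
    g = group_vector(design.n, design.group_allocation)
    means = np.column_stack(
        [
            np.full(design.n, pop.mu_I),
            pop.mu_LS + pop.beta * g,
            np.full(design.n, pop.mu_QS),
        ]
    )
    sds = np.sqrt([pop.var_I, pop.var_LS, pop.var_QS])
    eta = means + rng.standard_normal((design.n, 3)) * sds
    return eta, g


def generate_dataset(
    design: SimulationDesign,
    replicate_index: int = 0,
    basis: ContrastBasis | None = None,
) -> LongitudinalDataset:
    """Generate one replicate dataset; deterministic in (seed, replicate_index)."""
    if basis is None:
        basis = build_contrast_basis()
    eta, g = generate_factors(design, replicate_index)
    # y_i = Lambda @ eta_i  <=>  rows y = eta @ Lambda.T = eta @ C
    outcomes = eta @ basis.contrast_matrix
    return LongitudinalDataset(outcomes=outcomes, group=g)


def generate_study_scores(
    design: SimulationDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """All replicates of a design as stacked growth scores.

    Returns ``(scores, group)`` with ``scores`` of shape (n_reps, n, 3).
    Because the loading matrix is orthonormal and the generator draws the
    factors directly, the growth scores of a generated dataset are exactly
    those factor draws; we return them without a round trip through the
    outcome scale.
    """
    scores = np.empty((design.n_reps, design.n, 3))
    for r in range(design.n_reps):
        scores[r], g = generate_factors(design, r)
    return scores, group_vector(design.n, design.group_allocation)
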