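import numpy as np
import pytest

from bayesrma import (
    SimulationDesign,
    build_contrast_basis,
    default_population,
    generate_dataset,
)


@pytest.fixture(scope="session")
def basis():
    return build_contrast_basis()


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def small_dataset(population):
    """One n=8, balanced-group dataset from the default population."""
    design = SimulationDesign(population, n=8, group_allocation=0.5,
                              n_reps=1, seed=42)
    return generate_dataset(design, 0)


@pytest.fixture(scope="session")
def medium_dataset(population):
    """n=200 dataset, large enough that the likelihood dominates flat priors."""
    design = SimulationDesign(population, n=200, group_allocation=0.5,
                              n_reps=1, seed=7)
    return generate_dataset(design, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2718)
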