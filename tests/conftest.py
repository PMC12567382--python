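import numpy as np
import pytest

from nicheweave import climate, synthetic


@pytest.fixture(scope="session")
def small_grid():
    """Deterministic 12 x 10 climate grid with mild noise."""
    return synthetic.make_climate_grid(12, 10, seed=42)


@pytest.fixture(scope="session")
def predictors(small_grid):
    return climate.build_predictors(small_grid)


@pytest.fixture(scope="session")
def eco_map(small_grid):
    return synthetic.make_ecosystem_map(small_grid, k=3)


@pytest.fixture(scope="session")
def community(predictors):
    """Two ticks and four hosts with known Gaussian niches, plus truth."""
    taxa = synthetic.make_taxa(predictors, 2, 4, seed=7, breadth_scale=0.8)
    truth = synthetic.build_truth(taxa, predictors)
    return taxa, truth


@pytest.fixture(scope="session")
def host_tree():
    return synthetic.make_phylogeny([f"host_{i}" for i in range(8)], seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
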