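import numpy as np
import pandas as pd
import pytest

from occuedge.grid import GridSpec
from occuedge.model import DynamicOccupancyModel
from occuedge.pipeline import assemble
from occuedge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def small_config():
    """Small synthetic dataset: quick to simulate and fit."""
    return SimulationConfig(n_rows=10, n_cols=10, n_species=8, range_size_max=60,
                            range_size_log_mean=3.2)


@pytest.fixture(scope="session")
def small_sim(small_config):
    records, species_cells, cell_attrs, truth = simulate_dataset(small_config, seed=7)
    return records, species_cells, cell_attrs, truth


@pytest.fixture(scope="session")
def small_assembled(small_sim, small_config):
    records, species_cells, cell_attrs, _ = small_sim
    return assemble(records, species_cells, cell_attrs, small_config.grid, 1980)


@pytest.fixture(scope="session")
def small_dataset(small_assembled):
    return small_assembled[3]


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A quick real fit shared by product/diagnostic tests."""
    model = DynamicOccupancyModel(small_dataset)
    return model.fit(draws=400, burn=400, thin=1, chains=2, seed=42)


@pytest.fixture(scope="session")
def benchmark_fit():
    """The default synthetic benchmark fitted at the desk-scale settings.

    Expensive (a few minutes); shared between the convergence check and
    any test needing a converged full-size posterior.
    """
    cfg = SimulationConfig()
    records, species_cells, cell_attrs, truth = simulate_dataset(cfg, seed=1)
    _, _, _, dataset = assemble(records, species_cells, cell_attrs, cfg.grid, 1980)
    model = DynamicOccupancyModel(dataset)
    res = model.fit(draws=4000, burn=4000, thin=2, chains=3, seed=101)
    return res, truth


def make_random_pair_history(rng, max_surveys=4):
    """Random detection history + parameters for one species-cell pair."""
    n1 = int(rng.integers(0, max_surveys + 1))
    n2 = int(rng.integers(0, max_surveys + 1 - n1))
    y1 = rng.integers(0, 2, n1).astype(float)
    y2 = rng.integers(0, 2, n2).astype(float)
    p1 = rng.uniform(0.05, 0.95, n1)
    p2 = rng.uniform(0.05, 0.95, n2)
    psi, phi, gamma = rng.uniform(0.05, 0.95, 3)
    return y1, y2, p1, p2, psi, phi, gamma
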