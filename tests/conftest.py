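import numpy as np
import pytest
from hypothesis import settings

from tfinertia.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_motif_tables,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down synthetic study shared across test modules."""
    cfg = SimulationConfig(seed=42, n_genes=400, n_motifs=40)
    tables = simulate_motif_tables(cfg)
    expr, design, truth = simulate_expression(cfg, tables)
    return cfg, tables, expr, design, truth


def random_nonneg_table(rng, n, m, density=0.7):
    """Random nonnegative table with a positive grand total."""
    table = rng.random((n, m)) * (rng.random((n, m)) < density)
    table[0, 0] += 1.0  # guarantee a positive total
    return table
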