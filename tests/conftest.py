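import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", database=None, derandomize=True)
settings.load_profile("default")

from csphylo.simulate import (
    SimulationConfig,
    evolve_along_tree,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=10, gene_length_nt=300, read_length_nt=80,
        mean_depth=30.0, error_rate=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    records, _ = simulate_reference(small_config)
    return {r.gene_id: r.sequence for r in records}


@pytest.fixture(scope="session")
def four_species(small_config):
    """Two clades of two species each, at moderate divergence."""
    records, _ = simulate_reference(small_config)
    tree = "((A:0.04,B:0.04):0.04,(C:0.04,D:0.04):0.04);"
    return evolve_along_tree(records, tree, seed=6), tree


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
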