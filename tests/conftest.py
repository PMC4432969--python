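import pytest

from emtkit import SimulationConfig, simulate_expression, simulate_ppi


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation covering every downstream stage."""
    return SimulationConfig(
        seed=7, n_genes=600, n_pathways=8, n_signalling_pathways=5,
        pathway_size_range=(20, 60), network_size=120,
        planted_module_size=8, mean_cells_per_well=60.0,
        comparisons=("468_EGF", "468_HPX", "LA_EGF"),
    )


@pytest.fixture(scope="session")
def expression_sim(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def ppi_sim(small_config, expression_sim):
    return simulate_ppi(small_config, expression_sim)
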