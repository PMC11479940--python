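import pytest

from svakit.synthetic import SimConfig, simulate_genome_with_elements


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def genome_sim(sim_config):
    """Shared genome/elements/annotation/truth simulation."""
    return simulate_genome_with_elements(sim_config)
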