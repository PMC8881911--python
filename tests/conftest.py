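import pytest

import mockbias as mb
from mockbias.datasets import load_mock_design, load_trait_table


@pytest.fixture(scope="session")
def design():
    return load_mock_design()


@pytest.fixture(scope="session")
def traits():
    return load_trait_table()


@pytest.fixture(scope="session")
def experiment():
    """One seeded synthetic experiment at reduced depth, shared read-only."""
    params = mb.SimulationParams(seed=7, depth_mean=20_000, depth_sd=500)
    return mb.simulate_experiment(params)
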