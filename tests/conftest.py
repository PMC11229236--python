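import pytest

from peachbud import simulate as sim


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default simulated study, shared across tests."""
    return sim.simulate_all(seed=1)


@pytest.fixture(scope="session")
def default_config(default_dataset):
    return default_dataset["config"]
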