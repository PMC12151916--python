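import pytest

from telomir import synth


@pytest.fixture(scope="session")
def default_config() -> synth.SimulationConfig:
    return synth.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def genome(default_config):
    return synth.generate_genome(default_config)
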