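import pytest

from paleosize import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.default_config(seed=20260921)


@pytest.fixture(scope="session")
def fixture_tables(default_config):
    """One generated (observations, assemblage) pair shared across tests."""
    return (
        synth.generate_observations(default_config),
        synth.generate_assemblage(default_config),
    )
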