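import pytest

from matbgc.synthetic import ScenarioConfig


@pytest.fixture
def config() -> ScenarioConfig:
    """Default synthetic scenario, fixed seed."""
    return ScenarioConfig(seed=1)


@pytest.fixture
def quiet_config() -> ScenarioConfig:
    """Same scenario with every noise source switched off."""
    return ScenarioConfig(seed=1).noiseless()
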