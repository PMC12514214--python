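import pytest

from cmpkinetics import presets


@pytest.fixture(scope="session")
def phase1_pepsin_params():
    """Reference two-step shrinkage parameters for SGF + pepsin."""
    return presets.phase1_sgf_pepsin()


@pytest.fixture(scope="session")
def phase1_water_params():
    """Reference two-step shrinkage parameters for water at pH 2."""
    return presets.phase1_water_ph2()


@pytest.fixture(scope="session")
def phase3_params():
    """Reference pepsin-decay parameters (pre-acidified particle)."""
    return presets.phase3_preacidified()


@pytest.fixture(scope="session")
def system_config():
    """Reference stock-and-flow configuration (SGF + pepsin)."""
    return presets.system_sgf_pepsin()
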