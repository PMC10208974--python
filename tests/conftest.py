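import pytest
from hypothesis import settings

import foodcost as fc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny():
    """Hand-checkable 2-country, 4-group world (see docs/tiny_world.md)."""
    return fc.fixture_tiny()


@pytest.fixture(scope="session")
def world_small():
    """8-country synthetic world (2 per income group)."""
    cfg = fc.WorldConfig(seed=7, n_countries={"LIC": 2, "LMIC": 2, "UMIC": 2, "HIC": 2})
    return fc.generate_world(cfg)


@pytest.fixture(scope="session")
def world_default():
    """Default-size synthetic world (20 countries)."""
    return fc.generate_world(fc.WorldConfig(seed=11))
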