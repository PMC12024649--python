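import numpy as np
import pytest

from gcswitch import presets


@pytest.fixture(scope="session")
def auto_spec():
    return presets.autoactivator()


@pytest.fixture(scope="session")
def protease_spec():
    return presets.protease_switch()


@pytest.fixture(scope="session")
def two_component_spec():
    return presets.two_component()


@pytest.fixture(scope="session")
def lac_spec():
    return presets.lac()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
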