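import numpy as np
import pytest

from nervedce.protocol import DEFAULT_PROTOCOL
from nervedce.simulate import simulate_population_aif


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def dynamic_times(protocol):
    return protocol.dynamic_times_s()


@pytest.fixture(scope="session")
def population_aif(dynamic_times):
    """Default generative AIF on the protocol's dynamic grid."""
    return simulate_population_aif(dynamic_times)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
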