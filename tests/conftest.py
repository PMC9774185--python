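import numpy as np
import pytest
from hypothesis import settings

from pipgate.kinetics import sequential_open_scheme, two_state_scheme

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def worked_scheme():
    """Sequential C<->O1<->O2 chain with the worked rate set.

    At 20 uM: stationary weights (1, 2, 4)/7, Po = 6/7, mean closed 50 ms,
    mean open 300 ms.
    """
    return sequential_open_scheme(0.001, 0.01, 0.0005, 0.005)


@pytest.fixture(scope="session")
def simple_scheme():
    """Two-state C<->O scheme: opening 0.001*L /ms, closing 0.01 /ms."""
    return two_state_scheme(0.001, 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
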