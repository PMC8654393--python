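import numpy as np
import pytest

from microdcm import cmc, forward


@pytest.fixture(scope="session")
def rest_net():
    return cmc.rest_network()


@pytest.fixture(scope="session")
def rest_grid():
    return forward.rest_grid()


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    # compile the integrator once so individual test timings are meaningful
    net = cmc.rest_network()
    drive = np.zeros((11, 1))
    forward.integrate_time_domain(net, drive, dt=0.5)
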