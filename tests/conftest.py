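import numpy as np
import pytest

from slfv import EventKernel, Landscape, individuals_from_array


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_torus():
    return Landscape(2, (1.0, 1.0))


@pytest.fixture
def line_torus():
    return Landscape(1, (1.0,))


@pytest.fixture
def disc_kernel():
    return EventKernel("disc", radius=0.2, impact=0.5, rate_density=1.0)


@pytest.fixture
def gaussian_kernel():
    return EventKernel("gaussian", radius=0.1, impact=0.8, rate_density=2.0)


@pytest.fixture
def small_sample(unit_torus):
    locs = np.array([[0.1, 0.1], [0.2, 0.15], [0.6, 0.7], [0.8, 0.3]])
    return individuals_from_array(["a", "b", "c", "d"], locs)
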