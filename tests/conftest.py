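import numpy as np
import pytest

from critrange.kernels import uniform_box_kernel


@pytest.fixture(scope="session")
def k1d():
    return uniform_box_kernel(1, 1)


@pytest.fixture(scope="session")
def k2d():
    return uniform_box_kernel(2, 1)


@pytest.fixture(scope="session")
def k3d():
    return uniform_box_kernel(3, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
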