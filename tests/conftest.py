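import numpy as np
import pytest

from fwsafe import PhantomSpec, make_gradient_table, make_phantom
from fwsafe.io_core import ImageGrid


@pytest.fixture(scope="session")
def gtab():
    """Single-shell table: 1 b=0 + 41 directions at b=1000."""
    return make_gradient_table()


@pytest.fixture(scope="session")
def wm_tensor():
    """Axially symmetric WM-like tensor, principal axis along x."""
    return np.array([1.5e-3, 0.0, 0.0, 0.4e-3, 0.0, 0.4e-3])


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free phantom with lesions, shared across tests."""
    spec = PhantomSpec(shape=(24, 24, 24), rician_sigma=0.0, n_wmh=2, seed=7)
    return make_phantom(spec)


@pytest.fixture
def grid():
    return ImageGrid.isotropic((10, 10, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
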