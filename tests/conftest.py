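import numpy as np
import pytest

from svfatlas.fields import Image3D, VelocityField
from svfatlas.phantom import scaled_params
from svfatlas.registration import RegistrationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Phantom geometry scaled to a 32^3 grid."""
    return scaled_params((32, 32, 32))


@pytest.fixture
def tiny_params():
    """Phantom geometry scaled to a 16^3 grid."""
    return scaled_params((16, 16, 16))


@pytest.fixture
def fast_ssd_config():
    """Registration settings for quick, well-behaved phantom alignment."""
    return RegistrationConfig(similarity="ssd", levels=2, iters_per_level=40,
                              smooth_update_sigma=2.0, reg_weight=0.01,
                              step_size=0.3, converge_tol=1e-6)


def constant_svf(shape, vec):
    field = np.zeros(tuple(shape) + (3,))
    field[...] = np.asarray(vec, dtype=float)
    return VelocityField(field)


def smooth_image(shape, seed=0, sigma=3.0):
    from scipy import ndimage

    r = np.random.default_rng(seed)
    return Image3D(ndimage.gaussian_filter(r.standard_normal(shape), sigma))
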