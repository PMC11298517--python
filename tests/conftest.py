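import numpy as np
import pytest

from afspectra import NoiseModel, PhantomSpec, generate_liver_phantom
from afspectra.preprocess import fuse_bilateral_mcv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Small phantom in the noiseless, unattenuated, unshaded limit."""
    return PhantomSpec(
        shape_voxels=(16, 64, 64),
        noise_model=NoiseModel(gaussian_sd=0.0, poisson_scale=0.0),
        attenuation_length_um=np.inf,
        illumination_decay_um=np.inf,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_liver_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom under default (realistic) imaging conditions."""
    spec = PhantomSpec(shape_voxels=(16, 64, 64), seed=3)
    return spec, generate_liver_phantom(spec)


@pytest.fixture(scope="session")
def fused_small(small_phantom):
    _, (left, right, truth) = small_phantom
    return fuse_bilateral_mcv(left, right), truth
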