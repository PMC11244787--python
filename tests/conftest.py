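import numpy as np
import pytest

from ssefuse import GrayImage, PhantomSpec, generate_phantom_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair_small():
    """64x64 noiseless pair: fast enough for per-test use."""
    spec = PhantomSpec(size=(64, 64), seed=7, noise_sigma=0.0)
    return generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def phantom_pair_default():
    """The 256x256 default-spec pair used for frozen regressions."""
    return generate_phantom_pair(PhantomSpec())


def random_raw8(rng, shape=(16, 16)):
    return GrayImage(rng.integers(0, 256, size=shape).astype(float), "raw8")


def random_unit(rng, shape=(16, 16)):
    return GrayImage(rng.random(shape), "unit")
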