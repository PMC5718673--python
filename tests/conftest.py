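import numpy as np
import pytest

from lungreg import PhantomSpec, make_thorax
from lungreg.volumes import Volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110202)


@pytest.fixture(scope="session")
def thorax():
    """One noisy synthetic thorax shared by read-only tests."""
    return make_thorax(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def clean_thorax():
    """Noise-free thorax: voxel values take exactly the configured levels."""
    return make_thorax(PhantomSpec(noise_sd=0.0, seed=11))


def random_volume(rng, shape=(5, 4, 3), spacing=(1.0, 1.0, 1.0)):
    return Volume(rng.random(shape), spacing, normalized=True)


@pytest.fixture
def small_pair(rng):
    return random_volume(rng), random_volume(rng)
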