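import numpy as np
import pytest

from imiomics.imagecore import ScalarVolume
from imiomics.phantom import PhantomSpec, generate_subject


#: Coarse grid with the same physical extents as the default phantom; used
#: where shape realism matters but resolution does not.
SMALL_SPEC = PhantomSpec(shape=(32, 32, 80), spacing=(8.0, 8.0, 16.0))


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def noisefree_subject():
    return generate_subject(PhantomSpec(noise_sigma=0.0), seed=1)


@pytest.fixture(scope="session")
def small_subject():
    return generate_subject(SMALL_SPEC, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ScalarVolume(np.asarray(values, dtype=float), spacing, origin)
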