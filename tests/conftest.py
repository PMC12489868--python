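import numpy as np
import pytest

from mocs_clahe import GrayImage, PhantomSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vessel_phantom():
    """A 96x96 correct-exposure noisy vessel phantom used across modules."""
    return generate_phantom(PhantomSpec(width=96, height=96, seed=7)).image


@pytest.fixture()
def random_image(rng):
    return GrayImage(rng.random((16, 16)))
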