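import numpy as np
import pytest

from eclare import PhantomSpec, Volume, make_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Standard 64^3 isotropic test phantom."""
    return make_phantom(PhantomSpec(shape=(64, 64, 64), seed=7))


@pytest.fixture(scope="session")
def phantom32():
    """Small phantom for quick training-path tests."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32), seed=3))


@pytest.fixture()
def constant_volume():
    return Volume(np.full((16, 16, 24), 7.0), (1.0, 1.0, 1.0), through_axis=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
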