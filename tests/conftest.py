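import numpy as np
import pytest

from sphfod import sphharm


@pytest.fixture(scope="session")
def sampling_724():
    return sphharm.make_sampling(724, "fibonacci", lmax=8)


@pytest.fixture(scope="session")
def sampling_128():
    return sphharm.make_sampling(128, "fibonacci", lmax=8)


@pytest.fixture(scope="session")
def dense_sampling():
    """10,000-point well-spread sampling for quadrature-grade checks."""
    return sphharm.make_sampling(10000, "fibonacci", lmax=8)


@pytest.fixture(scope="session")
def icosphere_2562():
    return sphharm.make_sampling(2562, "icosphere", lmax=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
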