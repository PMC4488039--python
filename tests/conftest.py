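import numpy as np
import pytest
from shapely.geometry import box

from limnodb.fixtures import gen_landscape
from limnodb.vocabulary import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def landscape():
    return gen_landscape(n_lakes=30, extent_m=20000.0, seed=7)


@pytest.fixture
def unit_square():
    return box(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
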