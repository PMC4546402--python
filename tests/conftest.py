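import numpy as np
import pytest

from tmbundle import RestraintSet, btl_helices, square_bundle


@pytest.fixture(scope="session")
def specs():
    return btl_helices()


@pytest.fixture
def bundle(specs):
    return square_bundle(specs, side=9.0)


@pytest.fixture
def restraints():
    return RestraintSet()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
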