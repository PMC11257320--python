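import numpy as np
import pytest

from bilat_or import fixture
from bilat_or.likelihood import Group


@pytest.fixture(scope="session")
def aom():
    return fixture("aom")


@pytest.fixture(scope="session")
def myopia():
    return fixture("myopia")


@pytest.fixture
def rng():
    return np.random.default_rng(20240718)


def random_group(rng, max_count=20, allow_empty=False) -> Group:
    while True:
        g = Group(*(int(x) for x in rng.integers(0, max_count + 1, 5)))
        if allow_empty or g.n_tot + g.m_tot > 0:
            return g
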