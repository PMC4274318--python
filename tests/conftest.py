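import numpy as np
import pytest

from spindock.fixtures import FixtureSpec, make_exposed_site, make_toy_dimer


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(FixtureSpec())


@pytest.fixture(scope="session")
def exposed_site():
    return make_exposed_site()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
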