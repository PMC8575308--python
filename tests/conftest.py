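import numpy as np
import pytest

from metaglv.ensemble import Community, DispersalProfile, sample_interaction_matrix
from metaglv.grids import GridGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ring5():
    return GridGeometry.ring(5)


@pytest.fixture
def single_point():
    return GridGeometry.single_point()


@pytest.fixture
def logistic_community():
    """One species, r = K = 1, no interactions."""
    return Community(N=1, A=np.zeros((1, 1)), sigma=0.0, c=0.0, mu=0.0)


@pytest.fixture
def small_community():
    """Seeded N=6 community at moderate interaction strength."""
    A = sample_interaction_matrix(6, 0.5, -0.5, seed=7)
    return Community(N=6, A=A, sigma=0.05)


@pytest.fixture
def pair_community():
    """Two species, all-pairs -1 interactions (closed-form boundary at 1)."""
    A = np.array([[0.0, -1.0], [-1.0, 0.0]])
    return Community(N=2, A=A, sigma=0.0, c=1.0, mu=-1.0)


@pytest.fixture
def zero_dispersal():
    def make(n):
        return DispersalProfile(D=np.zeros(n), mu_D=0.0)

    return make
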