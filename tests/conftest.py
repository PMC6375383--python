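import numpy as np
import pytest

from spatialrecovery import Domain, GrowthModel, ModelParams


@pytest.fixture
def logistic():
    return GrowthModel(kind="power_logistic", K=1.0, gamma=0.0)


@pytest.fixture
def power3():
    return GrowthModel(kind="power_logistic", K=1.0, gamma=3.0)


@pytest.fixture
def bistable():
    return GrowthModel(kind="bistable", K=1.0, allee=0.3)


@pytest.fixture
def small_lattice():
    return Domain.lattice(100.0, 200, boundary="periodic")


@pytest.fixture
def path3():
    """3-node path network 0-1-2."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return Domain.network(A)
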