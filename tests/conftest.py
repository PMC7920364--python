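import numpy as np
import pytest

from tanwell import Geometry, build_grid, default_dimensionless_parameters


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def grid(geometry):
    return build_grid(geometry, 0.01)


@pytest.fixture(scope="session")
def params():
    # frozen dataclass: safe to share across tests
    return default_dimensionless_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
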