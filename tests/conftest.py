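import numpy as np
import pytest

from socassim.column import Forcing
from socassim.grid import PoolLayout, build_grid


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def layout(grid):
    return PoolLayout(n_layers=grid.n_layers)


@pytest.fixture()
def forcing(grid):
    """A mild temperate forcing: ~500 g C m-2 yr-1 NPP, 10 degC, -0.5 MPa."""
    n = grid.n_layers
    return Forcing(
        npp=500.0 / 365.0,
        soil_temperature=np.full(n, 10.0),
        soil_water_potential=np.full(n, -0.5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
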