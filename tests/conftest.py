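import numpy as np
import pytest

from fxsim.grid import GridSpec
from fxsim.landscape import generate_climate, generate_landscape
from fxsim.species import default_species


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(40, 40)


@pytest.fixture(scope="session")
def small_state(small_grid, species):
    return generate_landscape(small_grid, species, seed=7)


@pytest.fixture(scope="session")
def medium_state(species):
    return generate_landscape(GridSpec(100, 100), species, seed=3)


@pytest.fixture(scope="session")
def hot_dry_climate():
    return generate_climate("hot-dry", seed=3)


@pytest.fixture
def all_stockable(small_grid):
    return np.ones(small_grid.shape, dtype=np.uint8)
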