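import numpy as np
import pytest

import rewildmap as rw


@pytest.fixture(scope="session")
def scenario():
    """The reference synthetic study: (habitat, boundary, tracking)."""
    return rw.standard_scenario(seed=0)


@pytest.fixture(scope="session")
def habitat(scenario):
    return scenario[0]


@pytest.fixture(scope="session")
def boundary(scenario):
    return scenario[1]


@pytest.fixture(scope="session")
def tracking(scenario):
    return scenario[2]


@pytest.fixture(scope="session")
def proportions(habitat):
    """The 30 m aggregated cover raster of the reference landscape."""
    return rw.aggregate_proportions(habitat, 2)


@pytest.fixture
def small_grid():
    return rw.GridSpec(0.0, 300.0, 30.0, 10, 10)


@pytest.fixture
def uniform_forest_proportions(small_grid):
    """One-hot broadleaf-forest cover everywhere on a small grid."""
    cat = rw.ClassCatalogue()
    fr = np.zeros((len(cat), *small_grid.shape))
    fr[cat.index("broadleaf forest")] = 1.0
    return rw.ProportionRaster(small_grid, fr, cat)
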