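import logging

import numpy as np
import pytest

import timbersim as ts
from timbersim.landscape import LandCover, RoadClass, Zoning

logging.getLogger("timbersim").setLevel(logging.ERROR)


def uniform_grid(n=11, volume=30.0, cover=LandCover.FOREST, zoning=Zoning.PRIVATE_NONPROTECTED, cell_area=100.0):
    """A featureless landscape: handy for closed-form cost checks."""
    shape = (n, n)
    return ts.LandscapeGrid(
        volume=np.full(shape, float(volume)),
        land_cover=np.full(shape, int(cover), dtype=np.int16),
        zoning=np.full(shape, int(zoning), dtype=np.int16),
        roads=np.full(shape, int(RoadClass.NONE), dtype=np.int16),
        cell_area=cell_area,
    )


@pytest.fixture
def tiny_oracle():
    return ts.generate_fixture("tiny_oracle")


@pytest.fixture
def leakage_demo():
    return ts.generate_fixture("leakage_demo")


@pytest.fixture
def two_centers():
    return ts.generate_fixture("two_centers")


@pytest.fixture(scope="session")
def synthetic_100():
    """One 100x100 synthetic landscape shared by the long-run property tests."""
    spec = ts.LandscapeSpec(n_rows=100, n_cols=100, seed=3, mean_forest_volume=25.0)
    return ts.generate_landscape(spec), spec


@pytest.fixture(scope="session")
def full_cycle_pair(synthetic_100):
    """Full 30-year LEGAL/ILLEGAL ledgers on the shared 100x100 landscape."""
    (grid, centers), _ = synthetic_100
    params = ts.SimulationParams(rng_seed=3)
    return grid, centers, ts.run_pair(grid, centers, params)
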