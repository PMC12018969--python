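import numpy as np
import pytest

from ecoscape.grid_io import Grid, LandUseGrid
from ecoscape.synthetic import LandscapeSpec, generate_drivers, generate_landuse, generate_tables


@pytest.fixture(scope="session")
def small_spec() -> LandscapeSpec:
    return LandscapeSpec(shape=(60, 80), seed=7)


@pytest.fixture(scope="session")
def small_drivers(small_spec):
    return generate_drivers(small_spec)


@pytest.fixture(scope="session")
def small_landuse(small_spec, small_drivers) -> LandUseGrid:
    return generate_landuse(small_spec, small_drivers)


@pytest.fixture(scope="session")
def tables():
    return generate_tables(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_grid(values, cell_size=500.0, nodata=-9999.0) -> Grid:
    return Grid(np.asarray(values, dtype=float), cell_size=cell_size, nodata=nodata)


def make_landuse(values, cell_size=500.0) -> LandUseGrid:
    return LandUseGrid(np.asarray(values, dtype=np.int32), cell_size=cell_size)
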