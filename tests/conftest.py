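import numpy as np
import pytest

from tuces.ecoservices import BiophysicalTable
from tuces.raster import LandUseRaster, Raster
from tuces.synthetic import SyntheticConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Demo-scale study conditions: 20×20 grid, 9 cities, 3 years."""
    return SyntheticConfig(grid_rows=20, grid_cols=20, cell_area_km2=25.0,
                           n_cities=9, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def bio() -> BiophysicalTable:
    return BiophysicalTable.default()


@pytest.fixture
def uniform_raster():
    def make(value: float, shape=(10, 10), cell_area=1.0) -> Raster:
        return Raster(np.full(shape, float(value)), cell_area)
    return make


@pytest.fixture
def landuse_raster():
    def make(codes, cell_area=1.0, year=None) -> LandUseRaster:
        return LandUseRaster(np.asarray(codes, dtype=np.uint8), cell_area,
                             year=year)
    return make
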