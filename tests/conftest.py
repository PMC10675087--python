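from datetime import datetime, timezone

import numpy as np
import pytest

from laketwin.synth import make_basin_dem, make_bathymetry_points
from laketwin.terrain import (build_underwater_mesh, determine_lake_surface,
                              merge_twin)

AT = datetime(2021, 9, 17, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def cone_dem():
    """201x201 cone basin at 5 m cells, slope 0.01 (lake r = 100 L)."""
    dem, truth = make_basin_dem(shape=(201, 201), cell_size=5.0,
                                basin=("cone", 0.01))
    return dem, truth


@pytest.fixture(scope="session")
def cone_surface(cone_dem):
    dem, truth = cone_dem
    return determine_lake_surface(dem, 2.0, truth["center_xy"])


@pytest.fixture(scope="session")
def cone_twin(cone_dem, cone_surface):
    dem, _ = cone_dem
    bathy = make_bathymetry_points(dem, level=2.1, n_points=300, seed=1)
    mesh = build_underwater_mesh(bathy)
    return merge_twin(cone_surface, mesh, dem, AT)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
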