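"""Twin construction: water-level averaging, shoreline extraction,
bathymetric meshing and the mend/clip merge rules."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from laketwin.grids import ElevationGrid, GridGeometry
from laketwin.synth import make_basin_dem, make_bathymetry_points
from laketwin.terrain import (StaleLevelError, WaterLevelRecord,
                              build_underwater_mesh, determine_lake_surface,
                              mean_water_level, merge_twin, refresh_twin)

T0 = datetime(2021, 9, 17, 12, 0, tzinfo=timezone.utc)


def rec(station, hours_before, level):
    return WaterLevelRecord(station_id=station,
                            timestamp=T0 - timedelta(hours=hours_before),
                            level=level)


class TestMeanWaterLevel:
    @pytest.mark.parametrize("records,expected", [
        ([rec("a", 0, 8.0), rec("b", 0, 8.2), rec("c", 0, 8.4)], 8.2),
        ([rec("a", 0, 7.5)], 7.5),
        # hand-trace: station b's only reading is outside the 1 h window,
        # so only station a's 8.0 m counts
        ([rec("a", 0, 8.0), rec("b", 3, 8.6)], 8.0),
    ])
    def test_per_station_latest_then_mean(self, records, expected):
        assert mean_water_level(records, T0, window_hours=1.0) == \
            pytest.approx(expected)

    def test_latest_reading_per_station_wins(self):
        records = [rec("a", 2, 9.0), rec("a", 1, 8.0)]
        assert mean_water_level(records, T0, window_hours=6.0) == 8.0

    def test_all_stale_raises(self):
        with pytest.raises(StaleLevelError):
            mean_water_level([rec("a", 10, 8.0)], T0, window_hours=6.0)


class TestLakeSurface:
    def test_cone_level_set_matches_analytic_circle(self):
        dem, truth = make_basin_dem(shape=(501, 501), cell_size=5.0,
                                    basin=("cone", 0.01))
        surf = determine_lake_surface(dem, 2.0, truth["center_xy"])
        assert surf.area_km2 == pytest.approx(np.pi * 0.04, rel=0.02)
        b = np.vstack(surf.boundary)
        cx, cy = truth["center_xy"]
        r = np.hypot(b[:, 0] - cx, b[:, 1] - cy)
        assert abs(r.mean() - 200.0) / 200.0 < 0.015

    def test_area_identity(self, cone_surface):
        n = cone_surface.mask.sum()
        assert cone_surface.area_km2 == n * 25.0 / 1e6

    def test_seed_above_level_raises(self):
        geom = GridGeometry((0, 50), 5.0, (10, 10))
        dem = ElevationGrid(geometry=geom, values=np.full((10, 10), 10.0))
        with pytest.raises(ValueError, match="above the water level"):
            determine_lake_surface(dem, 9.0, (25.0, 25.0))

    def test_seed_outside_grid_raises(self, cone_dem):
        dem, _ = cone_dem
        with pytest.raises(IndexError):
            determine_lake_surface(dem, 2.0, (-1e5, -1e5))

    def test_two_basins_flood_only_seeded_one(self):
        # hand-built 10x10: two depressions split by a high ridge
        z = np.full((10, 10), 5.0)
        z[2:4, 2:4] = 0.0   # basin A
        z[6:8, 6:8] = 0.0   # basin B
        geom = GridGeometry((0, 100), 10.0, (10, 10))
        dem = ElevationGrid(geometry=geom, values=z)
        surf = determine_lake_surface(dem, 1.0, geom.cell_center(2, 2))
        expected = np.zeros((10, 10), bool)
        expected[2:4, 2:4] = True
        assert (surf.mask == expected).all()

    def test_level_monotonicity(self, cone_dem):
        dem, truth = cone_dem
        seed = truth["center_xy"]
        m1 = determine_lake_surface(dem, 1.0, seed).mask
        m2 = determine_lake_surface(dem, 2.0, seed).mask
        assert (m1 <= m2).all() and m2.sum() > m1.sum()


class TestUnderwaterMesh:
    def test_unit_square_two_triangles_flat(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
        mesh = build_underwater_mesh(pts)
        assert len(mesh.faces) == 2
        assert (mesh.vertices[:, 2] == 0).all()

    def test_plane_interpolated_exactly(self, rng):
        xy = rng.uniform(0, 100, size=(40, 2))
        pts = np.column_stack([xy, xy[:, 0] + 2 * xy[:, 1]])
        mesh = build_underwater_mesh(pts)
        qx, qy = rng.uniform(20, 80, size=(2, 25))
        z = mesh.interpolate(qx, qy)
        np.testing.assert_allclose(z, qx + 2 * qy, atol=1e-9)

    def test_input_heights_reproduced_exactly(self, rng):
        pts = rng.uniform(0, 100, size=(30, 3))
        mesh = build_underwater_mesh(pts)
        np.testing.assert_array_equal(mesh.vertices, pts)

    def test_collinear_points_raise(self):
        pts = [(0, 0, 1), (1, 1, 2), (2, 2, 3)]
        with pytest.raises(ValueError):
            build_underwater_mesh(pts)


class TestMergeTwin:
    def _ring_mesh(self, cone_dem, r_max, z_from_r):
        _, truth = cone_dem
        cx, cy = truth["center_xy"]
        rng = np.random.default_rng(3)
        rr = np.sqrt(rng.uniform(0, 1, 400)) * r_max
        th = rng.uniform(0, 2 * np.pi, 400)
        ring_t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rr = np.concatenate([rr, np.full(200, r_max)])
        th = np.concatenate([th, ring_t])
        x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
        return build_underwater_mesh(np.column_stack([x, y, z_from_r(rr)]))

    def test_mend_fills_annulus(self, cone_dem, cone_surface):
        dem, _ = cone_dem
        mesh = self._ring_mesh(cone_dem, 150.0, lambda r: 0.01 * r)
        twin = merge_twin(cone_surface, mesh, dem, T0)
        assert "mend" in twin.provenance
        # merged planform must reach every water cell center
        from scipy.spatial import Delaunay
        rows, cols = np.nonzero(cone_surface.mask)
        cx, cy = dem.geometry.cell_center(rows, cols)
        tri = Delaunay(twin.underwater.vertices[:, :2])
        assert (tri.find_simplex(np.column_stack([cx, cy])) >= 0).all()

    def test_clip_drops_vertices_above_level(self, cone_dem, cone_surface):
        dem, _ = cone_dem
        mesh = self._ring_mesh(cone_dem, 300.0, lambda r: 0.01 * r)  # max z 3
        twin = merge_twin(cone_surface, mesh, dem, T0)
        assert "clip" in twin.provenance
        assert twin.underwater.vertices[:, 2].max() <= 2.0 + 1e-9

    def test_noop_returns_mesh_unchanged(self, cone_dem, cone_surface):
        dem, _ = cone_dem
        # footprint beyond every water cell center, all below the level
        mesh = self._ring_mesh(cone_dem, 205.0, lambda r: np.minimum(0.01 * r, 1.9))
        twin = merge_twin(cone_surface, mesh, dem, T0)
        assert twin.provenance == ()
        assert twin.underwater is mesh

    def test_mesh_entirely_above_level_raises(self, cone_dem, cone_surface):
        dem, _ = cone_dem
        mesh = self._ring_mesh(cone_dem, 150.0, lambda r: 5.0 + 0.01 * r)
        with pytest.raises(ValueError, match="entirely above"):
            merge_twin(cone_surface, mesh, dem, T0)


class TestRefreshTwin:
    def test_deterministic(self, cone_dem):
        dem, truth = cone_dem
        bathy = make_bathymetry_points(dem, 2.1, 200, seed=5)
        records = [rec("a", 0, 2.0), rec("b", 0, 2.0)]
        t1 = refresh_twin(dem, bathy, records, T0, truth["center_xy"])
        t2 = refresh_twin(dem, bathy, records, T0, truth["center_xy"])
        np.testing.assert_array_equal(t1.underwater.vertices,
                                      t2.underwater.vertices)
        assert (t1.surface.mask == t2.surface.mask).all()

    def test_rising_level_grows_area(self, cone_dem):
        dem, truth = cone_dem
        bathy = make_bathymetry_points(dem, 2.1, 200, seed=5)
        areas = []
        for level in (1.0, 1.5, 2.0):
            records = [rec("a", 0, level)]
            twin = refresh_twin(dem, bathy, records, T0, truth["center_xy"])
            areas.append(twin.surface.area_km2)
        assert areas[0] < areas[1] < areas[2]
        # analytic cone areas: pi (100 L)^2
        for a, level in zip(areas, (1.0, 1.5, 2.0)):
            assert a == pytest.approx(np.pi * (100 * level) ** 2 / 1e6,
                                      rel=0.02)
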