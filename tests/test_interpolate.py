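"""Ordinary kriging, nearshore fields and 3-D layer/section extraction."""

import warnings

import numpy as np
import pytest

from laketwin.grids import GridGeometry
from laketwin.interpolate import (Field3D, VariogramSpec, extract_layer,
                                  extract_section, fit_variogram, idw_2d,
                                  interpolate_3d, kriging_weights,
                                  nearshore_condition, ordinary_kriging_2d)

GEOM = GridGeometry((0.0, 1000.0), 20.0, (50, 50))


@pytest.fixture
def bump_samples(rng):
    xy = rng.uniform(50, 950, size=(30, 2))
    v = 0.2 + 0.5 * np.exp(-((xy[:, 0] - 400) ** 2 +
                             (xy[:, 1] - 600) ** 2) / (2 * 250 ** 2))
    return np.column_stack([xy, v])


class TestVariogram:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            VariogramSpec(nugget=-1)
        with pytest.raises(ValueError):
            VariogramSpec(nugget=2, sill=1)
        with pytest.raises(ValueError):
            VariogramSpec(model="cubic")

    def test_gamma_zero_at_origin_and_sill_beyond_range(self):
        spec = VariogramSpec(model="spherical", nugget=0.1, sill=1.0,
                             range_m=500)
        assert spec.gamma(0.0) == 0.0
        assert spec.gamma(500) == pytest.approx(1.0)
        assert spec.gamma(2000) == pytest.approx(1.0)

    def test_fit_recovers_reasonable_range(self, bump_samples):
        spec = fit_variogram(bump_samples)
        assert 0 <= spec.nugget <= spec.sill
        assert spec.range_m > 0


class TestOrdinaryKriging:
    def test_constant_field_preserved(self, rng):
        xy = rng.uniform(0, 1000, size=(12, 2))
        samples = np.column_stack([xy, np.full(12, 3.7)])
        fld = ordinary_kriging_2d(samples, GEOM,
                                  VariogramSpec(sill=1.0, range_m=400))
        np.testing.assert_allclose(fld.values, 3.7, atol=1e-8)

    def test_exact_at_sample_locations_with_zero_nugget(self, bump_samples):
        # evaluate the kriging predictor directly at a sample point
        spec = fit_variogram(bump_samples)
        spec = VariogramSpec(model=spec.model, nugget=0.0, sill=spec.sill,
                             range_m=spec.range_m)
        for i in (0, 7, 19):
            w, _ = kriging_weights(bump_samples, spec, bump_samples[i, :2])
            pred = w @ bump_samples[:, 2]
            assert pred == pytest.approx(bump_samples[i, 2], abs=1e-6)

    def test_weights_sum_to_one(self, bump_samples, rng):
        spec = fit_variogram(bump_samples)
        for _ in range(20):
            pt = rng.uniform(0, 1000, 2)
            w, _ = kriging_weights(bump_samples, spec, pt)
            assert abs(w.sum() - 1.0) <= 1e-9

    def test_duplicate_points_averaged_with_warning(self):
        samples = np.array([[10, 10, 1.0], [10, 10, 3.0], [500, 500, 2.0],
                            [900, 100, 4.0], [100, 900, 0.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            fld = ordinary_kriging_2d(samples, GEOM,
                                      VariogramSpec(sill=1, range_m=300))
        r, c = GEOM.index_of(10, 10)
        assert fld.values[r, c] == pytest.approx(2.0, abs=1e-6)

    def test_fewer_than_three_samples_falls_back_to_idw(self):
        with pytest.warns(UserWarning, match="inverse-distance"):
            fld = ordinary_kriging_2d(np.array([[100, 100, 1.0],
                                                [800, 800, 3.0]]), GEOM)
        v = fld.values
        assert np.nanmin(v) >= 1.0 - 1e-9 and np.nanmax(v) <= 3.0 + 1e-9
        assert fld.meta["method"] == "idw-fallback"

    def test_variance_positive_away_from_samples(self, bump_samples):
        spec = VariogramSpec(nugget=0.0, sill=0.1, range_m=400)
        fld = ordinary_kriging_2d(bump_samples, GEOM, spec)
        assert fld.variance[0, 0] > 0

    def test_idw_bounded_by_sample_range(self, rng):
        samples = np.column_stack([rng.uniform(0, 1000, (15, 2)),
                                   rng.uniform(2, 9, 15)])
        X, Y = GEOM.center_mesh()
        out = idw_2d(samples, X, Y)
        assert out.min() >= samples[:, 2].min() - 1e-9
        assert out.max() <= samples[:, 2].max() + 1e-9


class TestNearshore:
    def test_single_device_constant_band(self, cone_twin):
        sites = {"cam-0": (600.0, 500.0)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fld = nearshore_condition({"cam-0": 0.4}, sites, cone_twin,
                                      band_width_m=100.0)
        v = fld.values[np.isfinite(fld.values)]
        assert v.size > 0
        np.testing.assert_allclose(v, 0.4, atol=1e-9)

    def test_band_limit_covers_all_water(self, cone_twin):
        sites = {"cam-0": (600.0, 500.0)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fld = nearshore_condition({"cam-0": 0.4}, sites, cone_twin,
                                      band_width_m=1e9)
        assert np.isfinite(fld.values).sum() == cone_twin.surface.mask.sum()

    def test_overshoot_clamped_and_counted(self, cone_twin):
        # a tight spherical variogram with contrasting neighbours overshoots
        theta = 2 * np.pi * np.arange(12) / 12
        cx = cy = 502.5
        sites = {f"c{i}": (cx + 190 * np.cos(t), cy + 190 * np.sin(t))
                 for i, t in enumerate(theta)}
        vals = {f"c{i}": (0.95 if i % 2 else 0.02) for i in range(12)}
        fld = nearshore_condition(
            vals, sites, cone_twin, band_width_m=1e9,
            variogram=VariogramSpec(model="gaussian", nugget=0.0, sill=0.2,
                                    range_m=150.0))
        v = fld.values[np.isfinite(fld.values)]
        assert fld.meta["overshoots"] > 0
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_no_records_rejected(self, cone_twin):
        with pytest.raises(ValueError):
            nearshore_condition({}, {}, cone_twin)


def linear_field_3d(geometry=GEOM, depths=(0.5, 1.0, 1.5, 2.0), n_stations=8):
    theta = 2 * np.pi * np.arange(n_stations) / n_stations
    samples = []
    for t in theta:
        x, y = 500 + 300 * np.cos(t), 500 + 300 * np.sin(t)
        for d in depths:
            samples.append((x, y, d, 2.0 + 3.0 * d))
    return np.array(samples)


class TestInterpolate3D:
    def test_linear_in_depth_layer_means(self):
        f3 = interpolate_3d(linear_field_3d(), GEOM, [0.5, 1.0, 1.5, 2.0])
        for d, expected in [(0.5, 3.5), (1.0, 5.0), (1.5, 6.5)]:
            layer = extract_layer(f3, d)
            mean = np.nanmean(layer.values)
            assert mean == pytest.approx(expected, rel=0.05)

    def test_exact_at_sample_location(self):
        samples = linear_field_3d()
        f3 = interpolate_3d(samples, GEOM, [0.5, 1.0, 1.5, 2.0],
                            method="idw3d")
        # zero-distance short-circuit when a cell center hits a sample
        x, y, d, v = samples[0]
        r, c = GEOM.index_of(x, y)
        cxy = GEOM.cell_center(r, c)
        shifted = samples.copy()
        shifted[0, :2] = cxy
        f3 = interpolate_3d(shifted, GEOM, [0.5, 1.0, 1.5, 2.0],
                            method="idw3d")
        k = 0  # depth 0.5 level
        assert f3.values[k, r, c] == pytest.approx(shifted[0, 3])

    def test_single_sample_constant_field(self):
        f3 = interpolate_3d(np.array([[500.0, 500.0, 1.0, 4.2]]), GEOM,
                            [0.5, 1.0, 1.5])
        np.testing.assert_allclose(f3.values, 4.2, atol=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            interpolate_3d(np.empty((0, 4)), GEOM, [0.5])

    def test_bed_masking_below_bathymetry(self, cone_twin):
        geom = cone_twin.surface.geometry
        samples = linear_field_3d(geometry=geom)
        f3 = interpolate_3d(samples, geom, [0.5, 1.0, 1.5], twin=cone_twin)
        bed = cone_twin.bed_depth_grid()
        deepest = f3.values[-1]  # 1.5 m layer
        shallow_or_land = ~(bed >= 1.5)
        assert np.isnan(deepest[shallow_or_land]).all()


class TestSlicing:
    def _field(self):
        vals = np.stack([np.full(GEOM.shape, 4.0), np.full(GEOM.shape, 8.0)])
        return Field3D(geometry=GEOM, depth_levels=[1.0, 2.0], values=vals)

    def test_stored_level_returned_exactly(self):
        layer = extract_layer(self._field(), 1.0)
        np.testing.assert_array_equal(layer.values, 4.0)

    def test_midpoint_linear_interpolation(self):
        layer = extract_layer(self._field(), 1.5)
        np.testing.assert_allclose(layer.values, 6.0)

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_layer(self._field(), 5.0)

    def test_uniform_field_section_columns_identical(self):
        sec = extract_section(self._field(), [(100, 900), (900, 100)])
        for row, expected in zip(sec.values, (4.0, 8.0)):
            np.testing.assert_allclose(row[np.isfinite(row)], expected)

    def test_linear_depth_section_rows_constant_increasing(self):
        f3 = interpolate_3d(linear_field_3d(), GEOM, [0.5, 1.0, 1.5, 2.0])
        sec = extract_section(f3, [(300, 500), (700, 500)])
        means = np.nanmean(sec.values, axis=1)
        assert (np.diff(means) > 0).all()
        spread = np.nanstd(sec.values, axis=1)
        assert (spread < 0.05 * means).all()

    def test_degenerate_polylines_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            extract_section(self._field(), [(100, 100), (100, 100)])
        with pytest.raises(ValueError, match="outside"):
            extract_section(self._field(), [(1e6, 1e6), (2e6, 2e6)])
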