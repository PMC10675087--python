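"""Seeded generators for every input the pipeline consumes.

Each generator returns its artifact together with the ground truth that
produced it, so downstream recovery tests can score the pipeline against
known answers.  All generators are bit-reproducible under a fixed seed.

The default bundle mimics a realistic deployment at reduced spatial scale:
a conical basin with a planar water surface, 3 water-level gauges, a
bathymetric sounding set, one multiband reflectance scene with elliptical
bloom patches, 42 shoreline camera sites with synthetic frames, and 8
depth-profiling water-quality stations reporting every 4 hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .grids import ElevationGrid, GridGeometry, write_raster
from .satellite import HABMask, MultibandScene, MODIS_BANDS
from .terrain import WaterLevelRecord
from .video import Frame, SegmentationMask

__all__ = [
    "make_basin_dem", "make_bloom_scene", "make_camera_frames",
    "make_station_profiles", "make_water_levels", "make_bathymetry_points",
    "FixtureBundle", "make_bundle", "write_bundle",
]


def make_basin_dem(shape=(501, 501), cell_size: float = 5.0,
                   basin=("cone", 0.01), rim_elevation: float | None = None,
                   roughness_sd: float = 0.0, seed: int = 0):
    """Analytic basin DEM centered on the grid.

    ``basin`` is ``("cone", slope)`` (z = slope * r) or ``("paraboloid", a)``
    (z = a * r^2).  Returns ``(ElevationGrid, truth)`` where truth carries
    the analytic level-set radius ``r(L)``.
    """
    kind, param = basin
    if param <= 0:
        raise ValueError("basin parameter must be positive")
    nrow, ncol = shape
    if nrow < 101 or ncol < 101:
        raise ValueError("basin DEM must be at least 101x101")
    geometry = GridGeometry(origin_xy=(0.0, nrow * cell_size),
                            cell_size=cell_size, shape=(nrow, ncol))
    X, Y = geometry.center_mesh()
    cx = X[0, ncol // 2]
    cy = Y[nrow // 2, 0]
    r = np.hypot(X - cx, Y - cy)
    if kind == "cone":
        z = param * r
        radius_of_level = lambda L: L / param
    elif kind == "paraboloid":
        z = param * r ** 2
        radius_of_level = lambda L: float(np.sqrt(L / param))
    else:
        raise ValueError(f"unknown basin kind {kind!r}")
    if rim_elevation is not None:
        z = np.minimum(z, rim_elevation)
    if roughness_sd > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, roughness_sd, z.shape)
    dem = ElevationGrid(geometry=geometry, values=z)
    truth = {"kind": kind, "param": param, "center_xy": (float(cx), float(cy)),
             "radius_of_level": radius_of_level}
    return dem, truth


def make_water_levels(base_level: float, n_stations: int = 3,
                      start: datetime | None = None, hours: int = 24,
                      amplitude: float = 0.05, seed: int = 0):
    """Hourly per-station levels oscillating gently around a base level."""
    if start is None:
        start = datetime(2021, 9, 17, 0, 0, tzinfo=timezone.utc)
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, amplitude / 2, n_stations)
    records = []
    for h in range(hours):
        ts = start + timedelta(hours=h)
        for s in range(n_stations):
            level = base_level + offsets[s] + amplitude * np.sin(
                2 * np.pi * h / 24 + s)
            records.append(WaterLevelRecord(station_id=f"wl-{s}",
                                            timestamp=ts,
                                            level=float(level)))
    return records


def make_bathymetry_points(dem: ElevationGrid, level: float,
                           n_points: int = 400, margin_m: float = 0.0,
                           seed: int = 0) -> np.ndarray:
    """Soundings sampled from submerged DEM cells (bed = DEM here)."""
    wet = dem.valid_mask() & (dem.values <= level)
    rows, cols = np.nonzero(wet)
    if len(rows) < 3:
        raise ValueError("no submerged area to sound at this level")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=min(n_points, len(rows)), replace=False)
    x, y = dem.geometry.cell_center(rows[pick], cols[pick])
    z = dem.values[rows[pick], cols[pick]]
    return np.column_stack([x, y, z])


def make_bloom_scene(geometry: GridGeometry, wavelengths=MODIS_BANDS,
                     background: float = 0.05, patches=(),
                     noise_sd: float = 0.0, seed: int = 0,
                     timestamp: datetime | None = None):
    """Spectrally flat scene with elliptical NIR-uplift bloom patches.

    ``patches`` is a list of ``(cx, cy, rx, ry, uplift)``; outside patches
    the spectrum is flat so the floating-algae index is exactly zero.
    Returns ``(MultibandScene, truth HABMask)``.
    """
    red, nir, swir = wavelengths
    X, Y = geometry.center_mesh()
    truth = np.zeros(geometry.shape, dtype=bool)
    for cx, cy, rx, ry, uplift in patches:
        if uplift <= 0:
            raise ValueError("bloom NIR uplift must be positive")
        x0, y0 = geometry.origin_xy
        nrow, ncol = geometry.shape
        if not (x0 <= cx <= x0 + ncol * geometry.cell_size and
                y0 - nrow * geometry.cell_size <= cy <= y0):
            raise ValueError(f"patch center ({cx}, {cy}) outside grid")
        truth |= ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0
    rng = np.random.default_rng(seed)
    bands = {}
    for w in (red, nir, swir):
        b = np.full(geometry.shape, background)
        if noise_sd > 0:
            b = b + rng.normal(0.0, noise_sd, b.shape)
        bands[float(w)] = b
    uplift_field = np.zeros(geometry.shape)
    for cx, cy, rx, ry, uplift in patches:
        inside = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0
        uplift_field[inside] = np.maximum(uplift_field[inside], uplift)
    bands[float(nir)] = bands[float(nir)] + uplift_field
    scene = MultibandScene(bands=bands, geometry=geometry,
                           timestamp=timestamp, sensor_label="synthetic")
    mask = HABMask(mask=truth, threshold=float("nan"),
                   pixel_size=geometry.cell_size)
    return scene, mask


WATER_RGB = (70.0, 90.0, 110.0)
BLOOM_RGB = (60.0, 160.0, 70.0)


def _blob_mask(shape, fraction: float, rng) -> np.ndarray:
    """Connected-ish bloom mask with an exact pixel count.

    Threshold a smoothed random field at the quantile giving exactly
    ``round(fraction * N)`` pixels, so the realized coverage matches the
    schedule to within one pixel.
    """
    n = shape[0] * shape[1]
    k = int(round(fraction * n))
    if k == 0:
        return np.zeros(shape, dtype=bool)
    if k == n:
        return np.ones(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 8)
    order = np.argsort(fld.ravel())
    mask = np.zeros(n, dtype=bool)
    mask[order[-k:]] = True
    return mask.reshape(shape)


def make_camera_frames(fractions, size=(128, 128), noise_sd: float = 0.0,
                       seed: int = 0, device_ids=None,
                       start: datetime | None = None,
                       period_s: float = 1.0):
    """Synthetic nearshore frames: green bloom blobs on blue-gray water.

    One frame per scheduled coverage fraction; the truth mask realizes the
    fraction exactly (to one pixel).  Returns a list of
    ``(Frame, SegmentationMask)`` pairs.
    """
    fractions = list(fractions)
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("coverage fractions must lie in [0, 1]")
    if start is None:
        start = datetime(2021, 9, 17, 10, 0, tzinfo=timezone.utc)
    rng = np.random.default_rng(seed)
    pairs = []
    for i, f in enumerate(fractions):
        dev = device_ids[i] if device_ids is not None else f"cam-{i:02d}"
        ts = start + timedelta(seconds=i * period_s)
        truth = _blob_mask(size, f, rng)
        px = np.empty(size + (3,), dtype=float)
        for c in range(3):
            px[:, :, c] = np.where(truth, BLOOM_RGB[c], WATER_RGB[c])
        if noise_sd > 0:
            px = px + rng.normal(0.0, noise_sd, px.shape)
        frame = Frame(pixels=np.clip(px, 0, 255).astype(np.uint8),
                      device_id=dev, timestamp=ts)
        pairs.append((frame, SegmentationMask(mask=truth, device_id=dev,
                                              timestamp=ts)))
    return pairs


def make_station_profiles(sites, depths, field_fn=None,
                          parameter: str = "chl_a",
                          start: datetime | None = None, span_h: int = 24,
                          interval_h: int = 4, noise_sd: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Depth-profile station records sampled from an analytic field.

    ``sites`` maps station id -> (x, y); ``field_fn(x, y, d)`` gives the
    true concentration (default the linear profile 2 + 3 d).
    """
    if field_fn is None:
        field_fn = lambda x, y, d: 2.0 + 3.0 * d
    if start is None:
        start = datetime(2021, 9, 17, 0, 0, tzinfo=timezone.utc)
    rng = np.random.default_rng(seed)
    rows = []
    for h in range(0, span_h, interval_h):
        ts = start + timedelta(hours=h)
        for sid, (x, y) in sites.items():
            for d in depths:
                val = float(field_fn(x, y, d))
                if noise_sd > 0:
                    val += rng.normal(0.0, noise_sd)
                rows.append({"station_id": sid, "timestamp": ts.isoformat(),
                             "depth_m": float(d), "parameter": parameter,
                             "value": val})
    return pd.DataFrame(rows)


def _circle_sites(prefix: str, n: int, center, radius: float) -> dict:
    cx, cy = center
    theta = 2 * np.pi * np.arange(n) / n
    return {f"{prefix}-{i:02d}": (float(cx + radius * np.cos(t)),
                                  float(cy + radius * np.sin(t)))
            for i, t in enumerate(theta)}


@dataclass
class FixtureBundle:
    """One coherent synthetic study area with its ground truth."""

    seed: int
    dem: ElevationGrid
    dem_truth: dict
    level_records: list
    target_level: float
    bathymetry: np.ndarray
    scene: MultibandScene
    scene_truth: HABMask
    camera_sites: dict
    frame_pairs: list
    coverage_schedule: list
    station_sites: dict
    station_records: pd.DataFrame
    profile_truth: dict
    timestamp: datetime


def make_bundle(seed: int = 0, shape=(201, 201), cell_size: float = 5.0,
                slope: float = 0.01, level: float = 2.0,
                n_cameras: int = 42, n_quality_stations: int = 8,
                frame_size=(96, 96), frame_noise_sd: float = 0.0,
                scene_noise_sd: float = 0.0) -> FixtureBundle:
    """The default end-to-end fixture: cone lake plus all monitoring inputs.

    Deployment counts follow the study scale (42 cameras, 8 quality
    stations, 3 level gauges); spatial extent is a reduced cone basin so
    the whole pipeline runs in seconds.
    """
    at = datetime(2021, 9, 17, 12, 0, tzinfo=timezone.utc)
    dem, dem_truth = make_basin_dem(shape=shape, cell_size=cell_size,
                                    basin=("cone", slope))
    center = dem_truth["center_xy"]
    lake_r = level / slope

    levels = make_water_levels(base_level=level, n_stations=3,
                               amplitude=0.0, seed=seed)
    bathy = make_bathymetry_points(dem, level=level * 1.05,
                                   n_points=400, seed=seed + 1)
    scene, scene_truth = make_bloom_scene(
        dem.geometry, patches=[
            (center[0] - lake_r / 3, center[1], lake_r / 4, lake_r / 6, 0.05),
            (center[0] + lake_r / 3, center[1] + lake_r / 4,
             lake_r / 6, lake_r / 8, 0.08)],
        noise_sd=scene_noise_sd, seed=seed + 2, timestamp=at)

    camera_sites = _circle_sites("cam", n_cameras, center, lake_r * 0.95)
    rng = np.random.default_rng(seed + 3)
    theta = 2 * np.pi * np.arange(n_cameras) / n_cameras
    schedule = np.clip(0.25 + 0.2 * np.sin(theta)
                       + rng.normal(0, 0.02, n_cameras), 0.0, 1.0)
    frame_pairs = make_camera_frames(schedule, size=frame_size,
                                     noise_sd=frame_noise_sd, seed=seed + 4,
                                     device_ids=list(camera_sites),
                                     start=at)

    station_sites = _circle_sites("wq", n_quality_stations, center,
                                  lake_r * 0.5)
    profile_truth = {"formula": "2 + 3 * depth_m", "a": 2.0, "b": 3.0}
    records = make_station_profiles(station_sites,
                                    depths=[0.5, 1.0, 1.5],
                                    start=at - timedelta(hours=12),
                                    seed=seed + 5)
    return FixtureBundle(
        seed=seed, dem=dem, dem_truth=dem_truth, level_records=levels,
        target_level=level, bathymetry=bathy, scene=scene,
        scene_truth=scene_truth, camera_sites=camera_sites,
        frame_pairs=frame_pairs, coverage_schedule=list(map(float, schedule)),
        station_sites=station_sites, station_records=records,
        profile_truth=profile_truth, timestamp=at)


def write_bundle(bundle: FixtureBundle, out_dir) -> Path:
    """Serialize a bundle to the on-disk formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem = bundle.dem
    write_raster(out / "dem.tif", dem.values, dem.geometry,
                 crs_label=dem.crs_label)
    pd.DataFrame(
        [{"station_id": r.station_id, "timestamp": r.timestamp.isoformat(),
          "level_m": r.level} for r in bundle.level_records]
    ).to_csv(out / "water_levels.csv", index=False)
    pd.DataFrame(bundle.bathymetry, columns=["x", "y", "z"]).to_csv(
        out / "bathymetry.csv", index=False)

    scene = bundle.scene
    wavelengths = sorted(scene.bands)
    stack = np.stack([scene.bands[w] for w in wavelengths])
    write_raster(out / "scene.tif", stack, scene.geometry,
                 wavelengths_nm=wavelengths)

    frames_dir = out / "frames"
    frames_dir.mkdir(exist_ok=True)
    masks_dir = out / "truth_masks"
    masks_dir.mkdir(exist_ok=True)
    for frame, truth in bundle.frame_pairs:
        stamp = frame.timestamp.strftime("%Y%m%dT%H%M%S")
        name = f"{frame.device_id}_{stamp}.png"
        Image.fromarray(frame.pixels).save(frames_dir / name)
        Image.fromarray((truth.mask * 255).astype(np.uint8)).save(
            masks_dir / name)
    pd.DataFrame([{"device_id": d, "x": x, "y": y}
                  for d, (x, y) in bundle.camera_sites.items()]
                 ).to_csv(out / "camera_sites.csv", index=False)
    bundle.station_records.to_csv(out / "station_records.csv", index=False)
    pd.DataFrame([{"station_id": s, "x": x, "y": y}
                  for s, (x, y) in bundle.station_sites.items()]
                 ).to_csv(out / "station_sites.csv", index=False)

    truth = {
        "seed": bundle.seed,
        "basin": {k: v for k, v in bundle.dem_truth.items()
                  if k != "radius_of_level"},
        "target_level_m": bundle.target_level,
        "lake_radius_m": bundle.target_level / bundle.dem_truth["param"],
        "scene_bloom_pixels": int(bundle.scene_truth.mask.sum()),
        "scene_bloom_area_km2": bundle.scene_truth.area_km2,
        "coverage_schedule": bundle.coverage_schedule,
        "profile_truth": bundle.profile_truth,
        "timestamp": bundle.timestamp.isoformat(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out
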