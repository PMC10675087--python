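"""Digital twin of the lake body: surface, underwater terrain, merge rules.

The twin is rebuilt from three inputs whenever the water level changes:

1. the instantaneous water level, averaged over the latest reading of each
   gauging station within a staleness window;
2. the lake surface, the connected set of DEM cells at or below that level
   (flood fill from a seed point, 8-connectivity), with its boundary
   extracted as the iso-contour of the binary mask;
3. the underwater terrain, a Delaunay mesh over the bathymetric soundings,
   reconciled with the surface by two rules: *mend* (fill water cells the
   mesh does not reach with DEM cell-center vertices) and *clip* (drop mesh
   vertices above the water level).

The water surface is treated as planar; inputs share one vertical datum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage import measure

from .grids import ElevationGrid, GridGeometry

__all__ = [
    "WaterLevelRecord", "LakeSurface", "TerrainMesh", "TwinLakeModel",
    "StaleLevelError", "mean_water_level", "determine_lake_surface",
    "build_underwater_mesh", "merge_twin", "refresh_twin",
]

DEFAULT_WINDOW_HOURS = 6.0


class StaleLevelError(RuntimeError):
    """No water-level record falls inside the staleness window."""


@dataclass(frozen=True)
class WaterLevelRecord:
    station_id: str
    timestamp: datetime
    level: float  # meters above datum

    def __post_init__(self):
        if not np.isfinite(self.level):
            raise ValueError("water level must be finite")


def mean_water_level(records, at: datetime,
                     window_hours: float = DEFAULT_WINDOW_HOURS) -> float:
    """Arithmetic mean of the latest per-station level within the window.

    Stations whose newest reading is older than ``window_hours`` before
    ``at`` (or later than ``at``) are ignored; if every station is stale a
    :class:`StaleLevelError` is raised.
    """
    window = timedelta(hours=window_hours)
    latest: dict[str, WaterLevelRecord] = {}
    for rec in records:
        if rec.timestamp > at or at - rec.timestamp > window:
            continue
        cur = latest.get(rec.station_id)
        if cur is None or rec.timestamp > cur.timestamp:
            latest[rec.station_id] = rec
    if not latest:
        raise StaleLevelError(
            f"no water-level record within {window_hours} h of {at.isoformat()}")
    return float(np.mean([r.level for r in latest.values()]))


@dataclass
class LakeSurface:
    """Planar lake surface on the DEM grid at a given level."""

    level: float
    mask: np.ndarray            # boolean, True = water
    boundary: list              # closed polylines, each (k, 2) array of (x, y)
    geometry: GridGeometry
    area_km2: float = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        n = int(self.mask.sum())
        self.area_km2 = n * self.geometry.cell_size ** 2 / 1e6

    def boundary_geojson(self) -> dict:
        polys = [[[float(x), float(y)] for x, y in ring] for ring in self.boundary]
        if len(polys) == 1:
            geom = {"type": "Polygon", "coordinates": polys}
        else:
            geom = {"type": "MultiPolygon", "coordinates": [[p] for p in polys]}
        return {"type": "Feature", "geometry": geom,
                "properties": {"level_m": self.level, "area_km2": self.area_km2}}


def determine_lake_surface(dem: ElevationGrid, level: float,
                           seed_xy: tuple[float, float],
                           connectivity: int = 8) -> LakeSurface:
    """Lake surface as the flooded connected component containing the seed.

    Cells with elevation <= level count as water (ties flood).  The boundary
    is the 0.5 iso-contour of the binary mask, mapped to map coordinates.
    """
    wet = dem.valid_mask() & (dem.values <= level)
    r0, c0 = dem.geometry.index_of(*seed_xy)  # IndexError if outside
    if not wet[r0, c0]:
        raise ValueError(
            f"seed point {seed_xy} is above the water level ({level} m)")
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    labels, _ = ndimage.label(wet, structure=structure)
    mask = labels == labels[r0, c0]

    x0, y0 = dem.geometry.origin_xy
    cs = dem.geometry.cell_size
    boundary = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        # contour rows/cols are in array index space at cell centers
        x = x0 + (contour[:, 1] + 0.5) * cs
        y = y0 - (contour[:, 0] + 0.5) * cs
        boundary.append(np.column_stack([x, y]))
    return LakeSurface(level=level, mask=mask, boundary=boundary,
                       geometry=dem.geometry)


@dataclass
class TerrainMesh:
    """Triangulated terrain: vertices (n, 3) and triangle faces (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references invalid vertex")

    def interpolate(self, x, y):
        """Piecewise-linear height at query points (NaN outside the hull)."""
        from scipy.interpolate import LinearNDInterpolator
        f = LinearNDInterpolator(self.vertices[:, :2], self.vertices[:, 2])
        return f(np.asarray(x), np.asarray(y))

    def write_obj(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _triangulate(points_xy: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points_xy)
    except QhullError as err:
        raise ValueError(
            "bathymetry points are collinear or insufficient for meshing") from err
    # drop exactly degenerate (zero-area) triangles
    p = points_xy[tri.simplices]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    return tri.simplices[area2 > 0]


def build_underwater_mesh(points) -> TerrainMesh:
    """Delaunay mesh over (x, y) with bed elevation carried on vertices.

    Requires at least three non-collinear points; input heights are
    reproduced exactly at input locations (vertices are the inputs).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y, z) bathymetry points")
    faces = _triangulate(pts[:, :2])
    if len(faces) == 0:
        raise ValueError("bathymetry points are collinear")
    return TerrainMesh(vertices=pts, faces=faces)


@dataclass
class TwinLakeModel:
    """The digital lake twin at one timestamp: surface + submerged terrain."""

    timestamp: datetime
    level: float
    surface: LakeSurface
    underwater: TerrainMesh
    provenance: tuple[str, ...] = ()

    def bed_depth_grid(self) -> np.ndarray:
        """Water depth (m, positive down) at surface cells; NaN on land."""
        geom = self.surface.geometry
        X, Y = geom.center_mesh()
        z = self.underwater.interpolate(X.ravel(), Y.ravel()).reshape(X.shape)
        depth = self.level - z
        depth[~self.surface.mask] = np.nan
        return depth


def merge_twin(surface: LakeSurface, mesh: TerrainMesh, dem: ElevationGrid,
               timestamp: datetime, tol: float = 1e-9) -> TwinLakeModel:
    """Reconcile the underwater mesh with the instantaneous lake surface.

    Two branches, recorded in provenance:

    - ``clip``: vertices above the water level are dropped and the mesh is
      re-triangulated, so no retained vertex exceeds the level;
    - ``mend``: water cells whose centers the (clipped) mesh does not cover
      are filled with DEM cell-center vertices.

    If neither condition holds the input mesh is returned unchanged.
    """
    level = surface.level
    provenance: list[str] = []
    verts = mesh.vertices

    keep = verts[:, 2] <= level + tol
    if not keep.any():
        raise ValueError("underwater mesh lies entirely above the water level")
    if not keep.all():
        provenance.append("clip")
        verts = verts[keep]

    # does the mesh planform reach every water cell center?
    rows, cols = np.nonzero(surface.mask)
    cx, cy = surface.geometry.cell_center(rows, cols)
    uncovered = np.ones(len(rows), dtype=bool)
    if len(verts) >= 3:
        try:
            tri = Delaunay(verts[:, :2])
            uncovered = tri.find_simplex(np.column_stack([cx, cy])) < 0
        except QhullError:
            pass  # degenerate planform: everything uncovered -> mend
    if uncovered.any():
        provenance.append("mend")
        zfill = dem.values[rows[uncovered], cols[uncovered]]
        fill = np.column_stack([cx[uncovered], cy[uncovered], zfill])
        verts = np.vstack([verts, fill])

    if provenance:
        mesh = TerrainMesh(vertices=verts, faces=_triangulate(verts[:, :2]))
    return TwinLakeModel(timestamp=timestamp, level=level, surface=surface,
                         underwater=mesh, provenance=tuple(provenance))


def refresh_twin(dem: ElevationGrid, bathymetry, records, at: datetime,
                 seed_xy, window_hours: float = DEFAULT_WINDOW_HOURS,
                 connectivity: int = 8) -> TwinLakeModel:
    """Rebuild the twin for the water level prevailing at ``at``.

    Deterministic composition: mean level -> lake surface -> underwater
    mesh -> merge.
    """
    level = mean_water_level(records, at, window_hours=window_hours)
    surface = determine_lake_surface(dem, level, seed_xy,
                                     connectivity=connectivity)
    mesh = build_underwater_mesh(bathymetry)
    return merge_twin(surface, mesh, dem, at)
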