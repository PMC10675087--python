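"""Geostatistical fields: ordinary kriging of nearshore coverage ratios and
3-D water-quality fields with layer/section slicing.

Ordinary kriging is the classical exact interpolator: at each prediction
point the estimate is a weighted mean of the samples with weights solving

    [ Gamma  1 ] [ w  ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu ] = [ 1       ]

where ``Gamma`` holds pairwise semivariances ``gamma(h_ij)`` under a fitted
variogram model and the unit-sum constraint makes the estimator unbiased
(constant fields are preserved exactly).  The kriging variance
``w . gamma_0 + mu`` is returned alongside.

Depth-resolved station records are gridded into a 3-D field.  The default
method is separable: each station profile is first interpolated linearly in
depth onto the requested levels, then inverse-distance weighting spreads
each level horizontally.  Sparse profile monitoring (a handful of stations,
a few depths) resolves vertical structure far better than horizontal, and
the separable scheme preserves vertical gradients exactly where the field
varies only with depth; a scaled-coordinate anisotropic 3-D IDW is
available as an alternative (``method="idw3d"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grids import GridGeometry

__all__ = [
    "VariogramSpec", "Field2D", "Field3D", "SectionSlice",
    "fit_variogram", "kriging_weights", "ordinary_kriging_2d",
    "idw_2d", "nearshore_condition", "interpolate_3d",
    "extract_layer", "extract_section",
]


# --------------------------------------------------------------------------
# variogram models

@dataclass(frozen=True)
class VariogramSpec:
    """Parametric semivariogram: nugget at the origin rising to the sill
    over the correlation range (meters)."""

    model: str = "spherical"
    nugget: float = 0.0
    sill: float = 1.0
    range_m: float = 1000.0

    def __post_init__(self):
        if self.nugget < 0 or self.sill < self.nugget or self.range_m <= 0:
            raise ValueError("require 0 <= nugget <= sill and range > 0")
        if self.model not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"unknown variogram model {self.model!r}")

    def gamma(self, h):
        """Semivariance at lag h (gamma(0) = 0 by convention)."""
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        a = self.range_m
        if self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = psill * (1.5 * hr - 0.5 * hr ** 3)
        elif self.model == "exponential":
            g = psill * (1.0 - np.exp(-3.0 * h / a))
        else:  # gaussian
            g = psill * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        return np.where(h > 0, self.nugget + g, 0.0)


def fit_variogram(samples, model: str = "spherical",
                  n_bins: int = 12) -> VariogramSpec:
    """Weighted-least-squares fit of the empirical variogram.

    Bin pairwise lags, fit (nugget, partial sill, range) with weights
    proportional to pair counts.  Degenerate inputs (constant values, too
    few pairs) fall back to a benign default spec.
    """
    pts = np.asarray(samples, dtype=float)
    xy, z = pts[:, :2], pts[:, 2]
    d = cdist(xy, xy)
    iu = np.triu_indices(len(z), k=1)
    lags, sq = d[iu], 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    hmax = lags.max() if lags.size else 1.0
    default = VariogramSpec(model=model, nugget=0.0,
                            sill=max(float(np.var(z)), 1.0),
                            range_m=max(hmax / 2, 1.0))
    if lags.size < n_bins or np.var(z) < 1e-12:
        return default

    edges = np.linspace(0, hmax, n_bins + 1)
    idx = np.clip(np.digitize(lags, edges) - 1, 0, n_bins - 1)
    h_emp, g_emp, w_emp = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 2:
            h_emp.append(lags[sel].mean())
            g_emp.append(sq[sel].mean())
            w_emp.append(np.sqrt(sel.sum()))
    if len(h_emp) < 3:
        return default
    h_emp, g_emp, w_emp = map(np.asarray, (h_emp, g_emp, w_emp))

    def resid(p):
        nugget, psill, rng = p
        spec = VariogramSpec(model=model, nugget=nugget,
                             sill=nugget + psill, range_m=rng)
        return w_emp * (spec.gamma(h_emp) - g_emp)

    p0 = [0.0, max(g_emp.max(), 1e-6), max(hmax / 2, 1.0)]
    try:
        sol = least_squares(resid, p0,
                            bounds=([0, 1e-12, 1e-6],
                                    [np.inf, np.inf, 10 * hmax]))
        nugget, psill, rng = sol.x
    except Exception:
        return default
    if psill < 1e-12:
        return default
    return VariogramSpec(model=model, nugget=float(nugget),
                         sill=float(nugget + psill), range_m=float(rng))


# --------------------------------------------------------------------------
# 2-D fields

@dataclass
class Field2D:
    geometry: GridGeometry
    values: np.ndarray
    variance: np.ndarray | None = None
    parameter: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError("field shape does not match geometry")


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Average values sharing one location (exact duplicates make the
    kriging system singular)."""
    key = np.round(pts[:, :2], 9)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    if len(uniq) == len(pts):
        return pts
    warnings.warn("duplicate sample locations averaged before kriging")
    out = np.empty((len(uniq), pts.shape[1]))
    out[:, :2] = uniq
    for j in range(2, pts.shape[1]):
        out[:, j] = np.bincount(inv, weights=pts[:, j]) / np.bincount(inv)
    return out


def kriging_weights(samples, variogram: VariogramSpec, point):
    """Ordinary-kriging weights and Lagrange multiplier at one point.

    Exposed for verification: the weights sum to 1 by construction.
    """
    pts = np.asarray(samples, dtype=float)
    n = len(pts)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = variogram.gamma(cdist(pts[:, :2], pts[:, :2]))
    A[n, :n] = A[:n, n] = 1.0
    b = np.empty(n + 1)
    b[:n] = variogram.gamma(
        np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1]))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], float(sol[n])


def idw_2d(samples, X, Y, power: float = 2.0):
    """Inverse-distance-weighted prediction at arbitrary points."""
    pts = np.asarray(samples, dtype=float)
    d = cdist(np.column_stack([np.ravel(X), np.ravel(Y)]), pts[:, :2])
    out = np.empty(d.shape[0])
    zero = d < 1e-12
    has_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    w[has_zero] = 0.0
    out = (w @ pts[:, 2]) / w.sum(axis=1).clip(min=1e-300)
    for i in np.nonzero(has_zero)[0]:
        out[i] = pts[zero[i]][0, 2]
    return out.reshape(np.shape(X))


def ordinary_kriging_2d(samples, geometry: GridGeometry,
                        variogram: VariogramSpec | None = None,
                        cells_mask: np.ndarray | None = None,
                        parameter: str = "") -> Field2D:
    """Ordinary-kriging prediction (and variance) on every grid cell.

    Duplicate sample locations are averaged with a warning; fewer than
    three distinct samples falls back to inverse-distance weighting (with
    a warning, no variance).  With a nugget-free variogram the prediction
    reproduces sample values exactly at sample locations.
    """
    pts = _dedupe(np.asarray(samples, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("sample coordinates/values must be finite")
    X, Y = geometry.center_mesh()
    if cells_mask is None:
        cells_mask = np.ones(geometry.shape, dtype=bool)

    if len(pts) < 3:
        if len(pts) == 0:
            raise ValueError("no samples to interpolate")
        warnings.warn("fewer than 3 samples: inverse-distance fallback")
        vals = np.full(geometry.shape, np.nan)
        vals[cells_mask] = idw_2d(pts, X[cells_mask], Y[cells_mask])
        return Field2D(geometry=geometry, values=vals, parameter=parameter,
                       meta={"method": "idw-fallback"})

    if variogram is None:
        variogram = fit_variogram(pts)

    n = len(pts)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = variogram.gamma(cdist(pts[:, :2], pts[:, :2]))
    A[n, :n] = A[:n, n] = 1.0
    lu = lu_factor(A)

    q = np.column_stack([X[cells_mask], Y[cells_mask]])
    B = np.empty((n + 1, len(q)))
    B[:n] = variogram.gamma(cdist(pts[:, :2], q))
    B[n] = 1.0
    W = lu_solve(lu, B)                       # (n+1, m)
    pred = W[:n].T @ pts[:, 2]
    kvar = np.einsum("im,im->m", W[:n], B[:n]) + W[n]

    vals = np.full(geometry.shape, np.nan)
    var = np.full(geometry.shape, np.nan)
    vals[cells_mask] = pred
    var[cells_mask] = np.maximum(kvar, 0.0)
    return Field2D(geometry=geometry, values=vals, variance=var,
                   parameter=parameter,
                   meta={"method": "ordinary-kriging",
                         "variogram": variogram})


def nearshore_band(water_mask: np.ndarray, cell_size: float,
                   band_width_m: float) -> np.ndarray:
    """Water cells within ``band_width_m`` of the shoreline."""
    dist = ndimage.distance_transform_edt(water_mask) * cell_size
    return water_mask & (dist <= band_width_m)


def nearshore_condition(records, sites: dict, twin, band_width_m: float = 500.0,
                        variogram: VariogramSpec | None = None) -> Field2D:
    """Kriged coverage-ratio field on the nearshore band of the twin.

    ``records`` maps device id -> latest coverage record (or bare ratio);
    ``sites`` maps device id -> (x, y).  Values are clamped to [0, 1] after
    interpolation; the overshoot count is recorded in ``meta``.
    """
    samples = []
    for dev, rec in records.items():
        ratio = getattr(rec, "ratio", rec)
        x, y = sites[dev]
        samples.append((x, y, float(ratio)))
    if not samples:
        raise ValueError("no coverage records supplied")

    geom = twin.surface.geometry
    band = nearshore_band(twin.surface.mask, geom.cell_size, band_width_m)
    fld = ordinary_kriging_2d(samples, geom, variogram=variogram,
                              cells_mask=band, parameter="hab_coverage")
    inside = np.isfinite(fld.values)
    over = int(((fld.values > 1.0) | (fld.values < 0.0))[inside].sum())
    fld.values = np.where(inside, np.clip(fld.values, 0.0, 1.0), np.nan)
    fld.meta.update({"overshoots": over, "band_width_m": band_width_m})
    return fld


# --------------------------------------------------------------------------
# 3-D fields

@dataclass
class Field3D:
    geometry: GridGeometry
    depth_levels: np.ndarray        # meters below surface, strictly increasing
    values: np.ndarray              # (n_depth, n_row, n_col)
    parameter: str = ""

    def __post_init__(self):
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        if np.any(np.diff(self.depth_levels) <= 0):
            raise ValueError("depth levels must be strictly increasing")
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.depth_levels),) + tuple(self.geometry.shape)
        if self.values.shape != expect:
            raise ValueError("values shape must be (n_depth, rows, cols)")


def _profile_interp(depths: np.ndarray, vals: np.ndarray,
                    levels: np.ndarray) -> np.ndarray:
    """Linear interpolation along one station profile, end-clamped."""
    order = np.argsort(depths)
    return np.interp(levels, depths[order], vals[order])


def interpolate_3d(samples, geometry: GridGeometry, depth_levels,
                   method: str = "profile_idw", power: float = 2.0,
                   anisotropy: float = 100.0, twin=None,
                   parameter: str = "") -> Field3D:
    """Grid depth-resolved samples (x, y, depth, value) into a 3-D field.

    ``profile_idw`` (default): interpolate each station's profile linearly
    in depth onto the levels, then spread each level horizontally by IDW —
    exact at sample points when the sample depth is a stored level, and
    exact for fields varying only with depth.  ``idw3d``: inverse-distance
    weighting in scaled coordinates with depth stretched by ``anisotropy``
    (meters of horizontal distance per meter of depth).

    With ``twin`` given, cells below the local lake bed are masked NaN.
    """
    pts = np.asarray(samples, dtype=float)
    if pts.size == 0:
        raise ValueError("no samples to interpolate")
    if pts.ndim != 2 or pts.shape[1] != 4:
        raise ValueError("samples must be (x, y, depth, value)")
    if np.any(pts[:, 2] < 0):
        raise ValueError("depths must be non-negative (positive down)")
    levels = np.asarray(depth_levels, dtype=float)
    X, Y = geometry.center_mesh()
    nd = len(levels)
    out = np.empty((nd,) + tuple(geometry.shape))

    if method == "profile_idw":
        key = np.round(pts[:, :2], 9)
        stations, inv = np.unique(key, axis=0, return_inverse=True)
        prof = np.empty((len(stations), nd))
        for s in range(len(stations)):
            sel = inv == s
            prof[s] = _profile_interp(pts[sel, 2], pts[sel, 3], levels)
        for k in range(nd):
            layer_samples = np.column_stack([stations, prof[:, k]])
            out[k] = idw_2d(layer_samples, X, Y, power=power)
    elif method == "idw3d":
        scaled = pts[:, :3].copy()
        scaled[:, 2] *= anisotropy
        q = np.column_stack([np.tile(X.ravel(), nd),
                             np.tile(Y.ravel(), nd),
                             np.repeat(levels * anisotropy, X.size)])
        d = cdist(np.column_stack([q[:, 0], q[:, 1], q[:, 2]]), scaled)
        with np.errstate(divide="ignore"):
            w = 1.0 / d ** power
        zero = d < 1e-12
        has_zero = zero.any(axis=1)
        w[has_zero] = 0.0
        vals = (w @ pts[:, 3]) / w.sum(axis=1).clip(min=1e-300)
        for i in np.nonzero(has_zero)[0]:
            vals[i] = pts[zero[i]][0, 3]
        out = vals.reshape(nd, *geometry.shape)
    else:
        raise ValueError(f"unknown 3-D interpolation method {method!r}")

    if twin is not None:
        bed = twin.bed_depth_grid()
        for k, lev in enumerate(levels):
            below = ~(bed >= lev)  # NaN bed (land) also masks
            out[k][below] = np.nan
    return Field3D(geometry=geometry, depth_levels=levels, values=out,
                   parameter=parameter)


def extract_layer(field: Field3D, depth: float) -> Field2D:
    """Horizontal slice at a depth, linearly interpolated between levels."""
    lv = field.depth_levels
    if depth < lv[0] or depth > lv[-1]:
        raise ValueError(
            f"depth {depth} m outside stored levels [{lv[0]}, {lv[-1]}]")
    k = int(np.searchsorted(lv, depth))
    if k < len(lv) and lv[k] == depth:
        vals = field.values[k].copy()
    else:
        lo, hi = k - 1, k
        t = (depth - lv[lo]) / (lv[hi] - lv[lo])
        vals = (1 - t) * field.values[lo] + t * field.values[hi]
    return Field2D(geometry=field.geometry, values=vals,
                   parameter=field.parameter, meta={"depth_m": depth})


@dataclass
class SectionSlice:
    """Vertical curtain along a polyline: (depth x along-line) values."""

    distances: np.ndarray          # meters along the polyline
    depth_levels: np.ndarray
    values: np.ndarray             # (n_depth, n_sample)
    polyline: np.ndarray


def extract_section(field: Field3D, polyline, step: float | None = None) -> SectionSlice:
    """Sample the field on a vertical section along a polyline.

    Points are taken every ``step`` meters (default: one cell size) at every
    stored depth level; positions outside the grid or below the bed come
    back NaN.  A polyline entirely outside the grid, or of zero length,
    is an error.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total <= 0:
        raise ValueError("polyline has zero length")
    if step is None:
        step = field.geometry.cell_size
    s = np.arange(0.0, total + step / 2, step)
    s[-1] = min(s[-1], total)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1,
                      0, len(seglen) - 1)
    t = (s - cum[seg_idx]) / seglen[seg_idx]
    qx = poly[seg_idx, 0] + t * seg[seg_idx, 0]
    qy = poly[seg_idx, 1] + t * seg[seg_idx, 1]

    geom = field.geometry
    x0, y0 = geom.origin_xy
    cs = geom.cell_size
    # fractional array coordinates at cell centers
    col = (qx - x0) / cs - 0.5
    row = (y0 - qy) / cs - 0.5
    nrow, ncol = geom.shape
    inside = (row >= -0.5) & (row <= nrow - 0.5) & \
             (col >= -0.5) & (col <= ncol - 0.5)
    if not inside.any():
        raise ValueError("polyline lies entirely outside the grid")

    nd = len(field.depth_levels)
    vals = np.full((nd, len(s)), np.nan)
    rc = np.clip(row[inside], 0, nrow - 1)
    cc = np.clip(col[inside], 0, ncol - 1)
    r0 = np.floor(rc).astype(int)
    c0 = np.floor(cc).astype(int)
    r1 = np.minimum(r0 + 1, nrow - 1)
    c1 = np.minimum(c0 + 1, ncol - 1)
    fr, fc = rc - r0, cc - c0
    for k in range(nd):
        v = field.values[k]
        vals[k, inside] = ((1 - fr) * (1 - fc) * v[r0, c0]
                           + (1 - fr) * fc * v[r0, c1]
                           + fr * (1 - fc) * v[r1, c0]
                           + fr * fc * v[r1, c1])
    return SectionSlice(distances=s, depth_levels=field.depth_levels,
                        values=vals, polyline=poly)
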