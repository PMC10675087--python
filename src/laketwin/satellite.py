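"""Whole-lake bloom extent from multiband reflectance via the floating
algae index (FAI).

FAI is a linear-baseline-subtraction index: the NIR reflectance is compared
with the value predicted by the straight line joining the red and SWIR
bands,

    FAI = R_nir - R_red - (R_swir - R_red) * (l_nir - l_red) / (l_swir - l_red)

with l the band wavelengths.  Floating cyanobacterial scum raises NIR
reflectance above that baseline, so bloom pixels have FAI well above the
water background.  For sensors without a SWIR band (e.g. GOCI) an
NDVI-style fallback (R_nir - R_red) / (R_nir + R_red) is offered behind the
same interface and labelled in the summary.

Inputs are Rayleigh-corrected reflectances; atmospheric correction, cloud
masking and georegistration happen upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from skimage.filters import threshold_otsu

from .grids import GridGeometry

__all__ = ["MultibandScene", "FAIGrid", "HABMask", "MissingBandError",
           "compute_fai", "compute_ndvi_fallback", "classify_hab",
           "run_scene_monitoring", "MODIS_BANDS", "SENTINEL2_BANDS"]

MODIS_BANDS = (645.0, 859.0, 1240.0)      # red, NIR, SWIR (nm)
SENTINEL2_BANDS = (665.0, 865.0, 1610.0)


class MissingBandError(KeyError):
    pass


@dataclass
class MultibandScene:
    """Co-registered reflectance bands keyed by wavelength (nm)."""

    bands: dict[float, np.ndarray]
    geometry: GridGeometry
    timestamp: datetime | None = None
    sensor_label: str = "synthetic"
    nodata: float = float("nan")

    def __post_init__(self):
        shapes = {np.asarray(b).shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("bands differ in shape")
        if any(w <= 0 for w in self.bands):
            raise ValueError("wavelengths must be positive")
        self.bands = {float(w): np.asarray(b, dtype=float)
                      for w, b in self.bands.items()}

    def band(self, wavelength_nm: float) -> np.ndarray:
        try:
            return self.bands[float(wavelength_nm)]
        except KeyError:
            raise MissingBandError(
                f"scene has no band at {wavelength_nm} nm "
                f"(available: {sorted(self.bands)})") from None

    def valid_mask(self) -> np.ndarray:
        ok = np.ones(self.geometry.shape, dtype=bool)
        for b in self.bands.values():
            cur = np.isfinite(b)
            if not np.isnan(self.nodata):
                cur &= b != self.nodata
            ok &= cur
        return ok


@dataclass
class FAIGrid:
    values: np.ndarray
    geometry: GridGeometry
    wavelengths: tuple[float, float, float] | tuple[float, float]
    index_name: str = "FAI"


@dataclass
class HABMask:
    mask: np.ndarray
    threshold: float
    pixel_size: float
    area_km2: float = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_km2 = int(self.mask.sum()) * self.pixel_size ** 2 / 1e6


def compute_fai(scene: MultibandScene, red_nm: float, nir_nm: float,
                swir_nm: float) -> FAIGrid:
    """Per-pixel FAI; nodata pixels propagate as NaN."""
    if not (red_nm < nir_nm < swir_nm):
        raise ValueError("wavelength order must be red < NIR < SWIR")
    r, n, s = (scene.band(w) for w in (red_nm, nir_nm, swir_nm))
    frac = (nir_nm - red_nm) / (swir_nm - red_nm)
    fai = n - r - (s - r) * frac
    fai = np.where(scene.valid_mask(), fai, np.nan)
    return FAIGrid(values=fai, geometry=scene.geometry,
                   wavelengths=(red_nm, nir_nm, swir_nm))


def compute_ndvi_fallback(scene: MultibandScene, red_nm: float,
                          nir_nm: float) -> FAIGrid:
    """NDVI-style index for SWIR-less sensors; labelled distinctly."""
    r, n = scene.band(red_nm), scene.band(nir_nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = (n - r) / (n + r)
    idx = np.where(scene.valid_mask(), idx, np.nan)
    return FAIGrid(values=idx, geometry=scene.geometry,
                   wavelengths=(red_nm, nir_nm), index_name="NDVI-fallback")


def classify_hab(fai: FAIGrid, threshold: float = 0.0,
                 water_mask: np.ndarray | None = None) -> HABMask:
    """Bloom mask: index above threshold, restricted to water pixels."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = fai.values
    mask = np.isfinite(vals) & (vals > threshold)
    if water_mask is not None:
        water_mask = np.asarray(water_mask, dtype=bool)
        if water_mask.shape != mask.shape:
            raise ValueError("water_mask shape does not match index grid")
        mask &= water_mask
    return HABMask(mask=mask, threshold=threshold,
                   pixel_size=fai.geometry.cell_size)


def run_scene_monitoring(scene: MultibandScene, config: dict | None = None,
                         log: list | None = None):
    """Fully automatic scene run: index -> mask -> summary record.

    ``config`` keys: ``red_nm``/``nir_nm``/``swir_nm`` (default MODIS),
    ``threshold`` (scalar, default 0.0) or ``threshold: "otsu"`` for a
    per-scene Otsu split, ``water_mask``.  A summary dict is appended to
    ``log`` when given.
    """
    cfg = dict(config or {})
    red = cfg.get("red_nm", MODIS_BANDS[0])
    nir = cfg.get("nir_nm", MODIS_BANDS[1])
    swir = cfg.get("swir_nm", MODIS_BANDS[2])

    if float(swir) in scene.bands:
        fai = compute_fai(scene, red, nir, swir)
    else:
        warnings.warn(f"no SWIR band at {swir} nm; using NDVI-style fallback")
        fai = compute_ndvi_fallback(scene, red, nir)

    finite = np.isfinite(fai.values)
    valid = bool(finite.any())
    thr = cfg.get("threshold", 0.0)
    if thr == "otsu":
        thr = float(threshold_otsu(fai.values[finite])) if valid else 0.0
    mask = classify_hab(fai, float(thr), cfg.get("water_mask"))

    summary = {
        "timestamp": scene.timestamp.isoformat() if scene.timestamp else None,
        "sensor": scene.sensor_label,
        "index": fai.index_name,
        "threshold": float(thr),
        "pixels": int(mask.mask.sum()),
        "area_km2": mask.area_km2,
        "valid": valid,
    }
    if log is not None:
        log.append(summary)
    return fai, mask, summary
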