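"""Fusing satellite, camera and in-situ products into one ordered scene.

The three monitoring sources are stacked back-to-top in a fixed canonical
order — in-situ stations, then satellite extent, then camera coverage — so
that sparser layers are never hidden behind denser ones.  Fusion here is a
data structure plus a summary computation; rendering is delegated to the
exported GeoJSON/CSV artifacts.

The summary also operationalizes a subsurface early-warning rule: where
surface bloom coverage is low but subsurface chlorophyll-a is high, the
risk of imminent surfacing is flagged per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .interpolate import Field2D, Field3D, extract_layer
from .satellite import HABMask

__all__ = ["OverlayLayer", "OverlayStack", "SituationSummary",
           "assemble_overlay", "summarize_situation"]

ROLE_ORDER = ("in_situ", "satellite", "video")  # back -> top


@dataclass(frozen=True)
class OverlayLayer:
    role: str
    payload: object
    timestamp: datetime | None = None


@dataclass
class OverlayStack:
    layers: list[OverlayLayer]
    twin: object | None = None
    missing_roles: tuple[str, ...] = ()

    def layer(self, role: str) -> OverlayLayer | None:
        for lyr in self.layers:
            if lyr.role == role:
                return lyr
        return None


def _as_layers(role: str, payload) -> list[OverlayLayer]:
    if payload is None:
        return []
    if isinstance(payload, OverlayLayer):
        return [payload]
    if isinstance(payload, (list, tuple)) and \
            all(isinstance(p, OverlayLayer) for p in payload):
        return list(payload)
    ts = getattr(payload, "timestamp", None)
    return [OverlayLayer(role=role, payload=payload, timestamp=ts)]


def assemble_overlay(in_situ=None, satellite=None, video=None,
                     twin=None) -> OverlayStack:
    """Build the canonical back-to-top overlay stack.

    Arguments may arrive in any order/combination; the stored order is
    always in_situ, satellite, video.  Missing roles are allowed and
    recorded; two layers of one role sharing a timestamp are rejected.
    """
    provided = {"in_situ": _as_layers("in_situ", in_situ),
                "satellite": _as_layers("satellite", satellite),
                "video": _as_layers("video", video)}
    layers: list[OverlayLayer] = []
    for role in ROLE_ORDER:
        seen = set()
        for lyr in provided[role]:
            key = (role, lyr.timestamp)
            if key in seen:
                raise ValueError(
                    f"duplicate {role} layer at timestamp {lyr.timestamp}")
            seen.add(key)
            layers.append(OverlayLayer(role=role, payload=lyr.payload,
                                       timestamp=lyr.timestamp))
    if not layers:
        raise ValueError("no overlay layers supplied")
    missing = tuple(r for r in ROLE_ORDER if not provided[r])
    return OverlayStack(layers=layers, twin=twin, missing_roles=missing)


@dataclass
class SituationSummary:
    timestamp: datetime | None
    hab_area_km2: float | None = None
    coverage_max: float | None = None
    coverage_mean: float | None = None
    station_values: dict = field(default_factory=dict)
    risk_flags: np.ndarray | None = None
    n_risk_cells: int = 0
    missing_roles: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp.isoformat() if self.timestamp else None,
            "hab_area_km2": self.hab_area_km2,
            "coverage_max": self.coverage_max,
            "coverage_mean": self.coverage_mean,
            "station_values": self.station_values,
            "n_risk_cells": self.n_risk_cells,
            "missing_roles": list(self.missing_roles),
        }


def _surface_coverage_grid(stack: OverlayStack, shape) -> np.ndarray:
    """Best available per-cell surface bloom coverage in [0, 1]."""
    video = stack.layer("video")
    if video is not None and isinstance(video.payload, Field2D):
        cov = np.nan_to_num(video.payload.values, nan=0.0)
        if cov.shape == tuple(shape):
            return cov
    sat = stack.layer("satellite")
    if sat is not None and isinstance(sat.payload, HABMask) and \
            sat.payload.mask.shape == tuple(shape):
        return sat.payload.mask.astype(float)
    return np.zeros(shape)


def summarize_situation(stack: OverlayStack, field3d: Field3D | None = None,
                        risk_chl_threshold: float = float("inf"),
                        surface_low_threshold: float = 0.05,
                        risk_depth_m: float | None = None,
                        at: datetime | None = None) -> SituationSummary:
    """Aggregate the stack into one situation report.

    Whole-lake bloom area comes from the satellite layer, nearshore
    coverage extremes from the video layer, latest parameter values from
    the in-situ layer.  With a 3-D field present, a cell is risk-flagged
    when surface coverage < ``surface_low_threshold`` while subsurface
    chlorophyll-a at ``risk_depth_m`` (default: deepest stored level)
    exceeds ``risk_chl_threshold``.  Missing inputs yield absent fields,
    never errors; summarization is idempotent.
    """
    if not stack.layers:
        raise ValueError("empty overlay stack")
    summary = SituationSummary(timestamp=at, missing_roles=stack.missing_roles)

    sat = stack.layer("satellite")
    if sat is not None and isinstance(sat.payload, HABMask):
        summary.hab_area_km2 = sat.payload.area_km2

    video = stack.layer("video")
    if video is not None:
        payload = video.payload
        if isinstance(payload, Field2D):
            v = payload.values[np.isfinite(payload.values)]
            if v.size:
                summary.coverage_max = float(v.max())
                summary.coverage_mean = float(v.mean())
        elif isinstance(payload, (list, tuple)) and payload:
            ratios = [r.ratio for r in payload]
            summary.coverage_max = float(max(ratios))
            summary.coverage_mean = float(np.mean(ratios))

    in_situ = stack.layer("in_situ")
    if in_situ is not None and isinstance(in_situ.payload, dict):
        summary.station_values = dict(in_situ.payload)

    if field3d is not None and np.isfinite(risk_chl_threshold):
        depth = risk_depth_m if risk_depth_m is not None \
            else float(field3d.depth_levels[-1])
        sub = extract_layer(field3d, depth).values
        surface = _surface_coverage_grid(stack, field3d.geometry.shape)
        flags = (surface < surface_low_threshold) & \
            np.isfinite(sub) & (sub > risk_chl_threshold)
        summary.risk_flags = flags
        summary.n_risk_cells = int(flags.sum())
    return summary
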