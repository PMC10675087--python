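# Methods

This note records the models implemented in `laketwin`, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where more than one reasonable construction existed.

## Terrain twin

The lake is represented on the DEM raster grid in projected meters
(y north, half-open cell extents). The water surface is assumed planar:
one scalar level for the whole lake at a time, obtained as the arithmetic
mean of the newest reading per gauging station inside a staleness window
(`water_level.window_hours`, default 6 h — long enough to bridge ordinary
telemetry gaps in hourly gauging, short enough that a stuck station is
noticed). Records outside the window raise a stale-level error rather than
silently reusing old data. This planarity is a simplification: wind setup
and seiches tilt real lake surfaces, so levels near shore may deviate from
the lake-wide mean.

The lake surface is the 8-connected flood-filled component of cells with
elevation ≤ level containing a user seed point. Flood filling (rather than
a global threshold) excludes disconnected low-lying terrain elsewhere in
the watershed; ties at elevation == level count as water, consistent with
the ≤ in the clip rule. Island holes inside the component remain
non-water. The boundary is the 0.5 iso-contour of the binary mask, so its
positional accuracy is half a cell (2.5 m on a 5 m DEM); on the analytic
cone fixture the extracted radius converges to L/slope as the cell size
shrinks.

The underwater terrain is a 2-D Delaunay triangulation of the soundings
with bed elevation carried on vertices; linear interpolation on this mesh
is exact for planar beds and reproduces input points exactly. Merging
applies clip first (drop vertices above the level; error if nothing
remains submerged), then mend (any water-cell center outside the clipped
mesh's planform is filled with the DEM cell-center vertex, i.e. the
simplest densification consistent with the terrain source), then one final
re-triangulation. Provenance records which branches fired. Because mend
vertices come from cells already classified as water, the merged mesh
never violates the clip bound.

## Satellite extent

FAI is the linear-baseline index over red/NIR/SWIR Rayleigh-corrected
reflectance; it is invariant to spectrally flat additive offsets (a crude
aerosol term) and zero whenever NIR lies on the red–SWIR chord. Default
wavelengths are 645/859/1240 nm (MODIS); 665/865/1610 nm suits Sentinel-2
MSI. For SWIR-less sensors (GOCI) the same operation computes an
NDVI-style ratio instead and labels the summary accordingly, because FAI
is undefined without the SWIR anchor.

The bloom threshold is a configurable scalar (default 0.0, appropriate for
the noise-free synthetic scenes whose background FAI is exactly zero); an
Otsu per-scene mode exists for exploratory work. Published operational
thresholds are sensor- and atmosphere-specific, which is why none is
hard-coded. Area is pixel count × pixel area, exact by construction.
Atmospheric correction, cloud masking and georegistration are out of
scope; scenes are assumed co-registered with the DEM products.

## Camera coverage

Frames are center-cropped to the target aspect, bilinearly resized and
optionally normalized to [0, 1]; a frame already at the target size passes
through bit-identical, so preprocessing never degrades native-resolution
inputs. Segmentation is a contract (named, versioned, deterministic under
a fixed seed) with two implementations:

- **Green-excess baseline** — thresholds `G − (R+B)/2` on the [0, 1]
  channel scale (default 0.12). Surface cyanobacterial scum is strongly
  green-dominant against blue-gray water, so this is a deterministic,
  training-free reference used wherever tests must not depend on
  stochastic optimization.
- **Pixelwise logistic classifier** — trainable on (frame, labelled mask)
  pairs, features (R, G, B, green-excess), fitted by full-batch gradient
  descent with backtracking line search so the recorded training loss is
  non-increasing by construction; the pairs are split into train and
  validation sets (seeded, 25 % validation) and the validation F-score is
  reported on the fitted model. A degenerate all-background training set
  yields a constant background predictor with a warning. This is a linear
  per-pixel model: it learns color separation, not texture or context, and
  will underperform a convolutional encoder–decoder on frames where bloom
  and water overlap in color space.

Coverage is bloom pixels / total pixels per frame; stream monitoring
samples the first frame at or after each period boundary within a daily
window (default 08:00–18:00, matching daylight camera operation).
Precision/recall/F use the usual pixel tallies; the degenerate case with
no positive pixels anywhere is defined as F = 0 with a warning. TN is
tracked only to assert tally conservation.

## Geostatistics

**2-D.** Ordinary kriging with a spherical variogram fitted by weighted
least squares to the binned empirical variogram (weights ∝ √pair-count;
nugget ≥ 0, sill ≥ nugget, range > 0 enforced by the parameterization).
The augmented system is solved once per sample set (LU factorization) and
back-substituted for all prediction cells; weights sum to 1 by
construction, constant fields are preserved exactly, and a nugget-free
model is exact at sample locations. Exact duplicate locations are averaged
(the system is singular otherwise) with a warning; fewer than three
distinct samples falls back to inverse-distance weighting, which is
bounded by the sample range. Kriged coverage is clipped to the nearshore
band — water cells within `nearshore.band_m` (default 500 m) of shore —
because shoreline cameras only inform the nearshore zone; predictions
further into the lake would be extrapolation. Values are clamped to
[0, 1] after interpolation with overshoots counted in the field metadata.

**3-D.** Station profile data (a handful of stations × a few depths)
resolve vertical structure far better than horizontal. The default
gridding is therefore separable: each station profile is linearly
interpolated in depth onto the requested levels (end-clamped), then each
level is spread horizontally by IDW (power 2). This is the standard
profile-then-map practice in limnology/oceanography; it is exact at sample
points whose depth is a stored level and reproduces any field that varies
only with depth exactly — a single scaled-distance 3-D IDW cannot do this,
because at realistic station spacing the horizontal term dominates any
affordable vertical scaling and every layer collapses toward the global
sample mean. A scaled-coordinate anisotropic 3-D IDW (`method="idw3d"`,
`idw.anisotropy` meters of horizontal distance per meter of depth,
default 100) is retained for cases with genuinely 3-D sampling. Depth is
positive down from the instantaneous water surface; with a twin supplied,
cells below the local bed (level − mesh elevation) are masked NaN.

Layers at unsampled depths are linear interpolations of the bracketing
levels; sections sample every depth level along a polyline at a
configurable step (default one cell) with bilinear horizontal
interpolation, NaN outside the grid or below the bed.

## Fusion

The overlay stack stores at most one layer per role and timestamp in the
fixed order in-situ → satellite → video (back to top), invariant to
argument order; missing roles are recorded, never fatal. The situation
summary aggregates whole-lake bloom area (satellite), nearshore coverage
extremes (video) and latest surface values per station (in-situ), all
computed idempotently. The subsurface risk rule flags cells where surface
coverage < `surface_low_threshold` (default 0.05) while chlorophyll-a at a
chosen depth (default the deepest stored level) exceeds a user-set
threshold; the flag count is monotone non-increasing in that threshold.
The rule is an operationalization of the qualitative management heuristic
that high subsurface biomass under a clean surface precedes surfacing
events; the thresholds are management choices, not calibrated constants.

## Synthetic data

The generators emulate a full deployment at reduced spatial scale, with
counts matching a realistic large-lake installation: 42 shoreline cameras,
8 profiling stations, 3 level gauges, one reflectance scene. The basin is
analytic (cone z = s·r or paraboloid z = a·r²), so the level-set radius
and area are known in closed form. Bloom scenes are spectrally flat
(background FAI exactly 0) with elliptical NIR-uplift patches; camera
frames render bloom as green blobs (smoothed-noise quantile masks whose
pixel count matches the scheduled coverage to one pixel) on blue-gray
water; station records sample an analytic concentration field (default
c = 2 + 3·depth). All generators are bit-reproducible under a seed and
return their ground truth.

What passing these tests shows — and does not. The fixtures have sharp
color/spectral separation between bloom and water, planar or analytic
geometry and optional Gaussian noise only. Recovery there validates the
pipeline's arithmetic and geometry (index laws, area identities,
interpolation exactness, merge rules), not robustness to real-world
nuisances: sun glint, haze, mixed pixels, camera re-aiming, biofouling or
color-ambiguous scums. The trainable segmenter's high validation F on
synthetic frames reflects that separability and should not be read as a
field accuracy estimate.

## Problem sizes and numerics

Default test/acceptance sizes are chosen so the full suite and the
acceptance script each run in seconds on one CPU: 501×501 cells (5 m) for
the shoreline convergence check, 201×201 for twin/kriging fixtures,
50-cell interpolation grids, 96×96 frames, 42 sites, 400 soundings.
Tolerances: clip bound 1e−9; kriging weight-sum 1e−9 and sample exactness
1e−6 (linear-solve round-off); FAI laws 1e−12. Zero-distance IDW queries
short-circuit to the sample value. Degenerate variogram fits (constant
values, too few pairs) fall back to a benign default spec, which still
preserves constants and exactness.
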