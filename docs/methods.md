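# Methods

## Coordinate and unit conventions

All geometry is in millimetres in a right-handed frame. `z` increases
toward the proximal (beam-source) side, matching CT slice stacking, and the
electron beam central axis is fixed to `−z`. Arbitrary beam orientations
are handled by rigidly pre-rotating inputs (`geometry.apply_transform`), so
all slicing stays horizontal. Densities are g/cm³ (water = 1.0, printed ABS
1.05, paraffin 0.9), doses in Gy (or any unit; ΔD is a ratio).

## Contour-stack reconstruction

A bolus arrives as closed planar polygons on strictly increasing z levels,
one polygon per slice (the single-lobed case; branching stacks are rejected
loudly rather than mis-stitched). The solid is assembled as:

1. **Ring refinement.** Every slice ring is brought to one shared vertex
   count `n = max(64, ⌈perimeter / 0.5 mm⌉, raw vertex count)` (the max
   over slices). Refinement keeps every original vertex and distributes the
   extra vertices over edges by largest remainder on edge length, so the
   polygon geometry — area, perimeter, hence prism and frustum volume
   identities — is preserved *exactly*. A single shared count is what makes
   each intermediate ring common to the bands above and below it and thus
   the mesh watertight. (Equal-arc-length resampling is also provided as
   `resample_contour` for callers that want uniform spacing; it may cut
   corners of coarse polygons and is not used by the solid builder.)
2. **Correspondence.** Between adjacent rings the cyclic start offset is
   chosen by exhaustive search over all `n` offsets, minimising the summed
   squared vertex distance; ties break toward the smallest offset. No
   canonical inter-layer correspondence rule exists for this conversion;
   minimal-twist offset search is one defensible, fully deterministic
   realization.
3. **Band triangulation.** Each quad of the band is split along its shorter
   diagonal; rings are counter-clockwise so the band normals face outward.
4. **Caps.** First and last rings are closed with planar ear-clipping
   triangulations (area conserved to 1e-9 relative; a reflex vertex lying
   on a candidate diagonal blocks that ear, which keeps concave templates
   correct). Caps are flat at the slice plane — the TPS layer model has no
   end rounding.

The output must pass the watertightness census (every edge in exactly two
faces, once per direction, positive signed volume) or the builder raises.

## Reference bolus design

`design_reference_bolus` builds the solid bounded below by a bilinear skin
height map, above by the flat proximal plane `z = z_p`, laterally by the
(convex) aperture polygon. The skin surface is triangulated over the
aperture with scipy's Delaunay on the interior height-map nodes plus a
refined boundary ring, and the triangulation's boundary is *checked* to be
exactly the ring — if collinear ring points get bypassed by the convex
hull, the ring is retried with a sub-micron outward sine bulge (≤1e-6 mm,
orders of magnitude below the grid-resolution volume tolerance) that puts
the edge-interior points in strictly convex position. Convex apertures only
in v1: the clinical field shapes this targets (circular applicators,
rectangular inserts) all are, and convexity is what makes the
Delaunay-boundary argument sound. Designs with the proximal plane at or
below the skin maximum raise (negative thickness).

## Fabrication slicing

- Paraffin sheets: layer count `⌈height / 1.5 mm⌉` with the partial top
  sheet kept at its true thickness (volume conservation; how partial sheets
  were handled clinically is not documented, the ceiling rule is this
  package's choice). Template polygons are cross-sections at each layer's
  **mid-height**, making the staircase volume an unbiased estimate of the
  smooth volume; the staircase error decreases monotonically with sheet
  thickness (tested at 3 / 1.5 / 0.75 mm).
- The as-built staircase is the union of per-layer vertical prisms.
  Consecutive prisms occupy disjoint z bands, so the signed volume is
  exactly `Σ areaᵢ·thicknessᵢ`; coincident interface walls remain as
  internal face pairs, which keeps every component closed under the edge
  census.
- Print layers: `⌈height / 0.1 mm⌉` contours at layer mid-heights.

## Voxelization and the Matching Level

Point-in-solid tests use ray parity realised as planar cross-sections: for
each lattice z level the mesh section polygons are built once and all cell
centres are tested vectorised (shapely `contains_xy`). A plane that grazes
vertices or edges is retried at a fixed ±1e-6 mm offset, so results are
deterministic. Grids cover the mesh bounding box with a one-cell margin.

`matching_level` rasterises both meshes on one lattice anchored at the
combined bounding-box corner (default spacing 0.5 mm, a quarter of the
typical 2 mm CT slice; at that spacing the identical-mesh ML exceeds 99.9 %
and halving the spacing moves ML on smooth pairs by <0.5 percentage
points). Occupancy overlap was chosen over exact mesh booleans for
robustness on staircase/near-degenerate inputs; the lattice tolerance is
documented and tested instead of hidden. Note that
`ML = V1²/(Vr·V2)·100` is symmetric under swapping the two meshes — the
index penalises missing coverage and excess material simultaneously, which
is what distinguishes it from a one-sided coverage ratio (it is also not a
Dice coefficient).

`air_gap_fraction` quantifies bolus homogeneity (inspected only
qualitatively on CT in clinical practice) as the fraction of mesh-interior
voxels of a density grid below a threshold (default 0.5 g/cm³, comfortably
between air and both bolus materials).

## Registration

Landmark registration is the closed-form Kabsch/Umeyama solution with
scaling explicitly forbidden and reflections rejected — mirroring the
clinical three-points-on-the-bolus workflow. Collinear or <3
correspondences raise. The residual RMS is reported; no clinical threshold
is imposed since none is established for this workflow.

## Dose metrics and summaries

PTV metrics are min, D98 % (near-minimum), mean, D2 % (near-maximum), max.
D98/D2 follow ICRU-style robust extremes and are evaluated as dose-volume
percentiles with linear interpolation (`np.quantile` convention); absolute
min/max are also reported because both conventions are in clinical use.
Plan comparisons use the signed percentage ΔD = (Dr − Dm)/Dr·100, negative
when the fabricated-bolus plan delivers more dose.

Cohort columns are summarised with a Shapiro–Wilk gate at α = 0.05 (the
recorded normality outcome of a published cohort can be pinned with an
explicit mode override — recorded facts are not re-adjudicated). Quartiles
use rank position `(n+1)p` with linear interpolation; for n = 11 this makes
Q1/Q3 exactly the 3rd/9th order statistics, the convention that reproduces
every quartile pair in the packaged cohort. One packaged-cohort caveat: the
paraffin near-minimum column's reported median (7.0) equals its upper
quartile but not the median of its own values (4.0 under any standard
definition); the package reproduces the quartiles and flags that cell
rather than fitting an exotic median rule. Similarly, the cohort's reported
ML standard deviations do not recompute from the rounded printed columns,
and rows with `V1 = Vr = V2` at printed precision are rounding artifacts;
only self-consistent rows are used as exact anchors. Report-boundary
rounding is 1 decimal, half away from zero; internal computation keeps full
precision.

## Synthetic phantom and its limits

The phantom is a Gaussian skin valley (default depth 5 mm, width σ = 6 mm)
standing in for the canthus fold, under a 30 mm circular 6 MeV field —
matching the small-field clinical setting (cohort PTV depths 5.6–26 mm,
fields ~30 mm). The proximal plane is placed at `z_p = max(R90 − PTV depth,
2 mm)`, a geometric stand-in for conforming the 90 % isodose to the distal
PTV — no dosimetric optimisation is performed. The PTV is a skin-following
plug of radius aperture/4 from 0.5 mm to the configured depth below the
skin.

Paraffin degradation shifts each 1.5 mm sheet laterally by N(0, sd²)
(default sd 1.0 mm) and voids a fraction (default 5 %) of interior voxels
in the voxel slabs nearest sheet interfaces. Both knobs are free
parameters: no quantitative defect statistics exist for hand-layered
boluses, and these defaults were fixed once as a plausible manual-layering
error scale.

The toy dose engine maps water-equivalent depth along each `−z` column
(density × path length, midpoint rule per voxel) through a trapezoidal
electron PDD: linear build-up to `d100 = 0.6·R90`, unity plateau, linear
fall-off crossing 90 % at R90 and zero at Rp, with rule-of-thumb ranges
R90 ≈ E/4 cm and Rp ≈ E/2 cm (configurable). **It is a test harness, not a
dose engine**: no scatter, no lateral transport, no build-down, no output
factors. What passing tests show is that geometric fabrication defects
propagate into dose-metric differences with the right sign and ordering —
not that the magnitudes are clinically meaningful. Two known behaviours of
this model worth naming: lateral sheet shifts conserve bolus volume, so the
*mean* water-equivalent depth over the PTV is nearly shift-invariant and
|ΔD| is driven mainly by the density deficit and the interface voids; and
because the PDD plateau caps the dose, |ΔD| grows with the air-gap rate
only in the modest regime (≲7 %) and saturates beyond it. The monotonicity
property test is therefore formulated over the air-gap rate in that regime,
with fixed seeds.

Problem sizes used by the test suite and examples (30 mm fields, 0.5 mm
overlap lattices, 1 mm dose lattices, 10 seeds end-to-end) were chosen so
the full pipeline exercises every code path at sub-minute granularity while
remaining converged: the documented grid-convergence tests are the evidence
that these lattices are fine enough.

## Known limitations

- One contour per slice; holes/islands and branching topologies are out of
  scope, as are mesh repair, decimation and non-rigid registration.
- Convex apertures only in reference-bolus design.
- Minimal RTSTRUCT dialect: `CLOSED_PLANAR` contours for a named ROI only.
- The dose engine is 1-D in depth (see above); clinical dose must come from
  a TPS, whose grids this package merely consumes.
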