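"""Synthetic phantoms: canthus-like skin, degraded paraffin boluses, toy dose.

Everything needed to exercise the full design -> fabricate -> QA pipeline
without patient data: a Gaussian-valley skin surface standing in for the
medial/lateral eye canthus, a reference bolus designed against it, a
"paraffin" bolus degraded by per-sheet lateral shifts and interface air
gaps, and a deliberately simple parametric electron depth-dose engine.

The dose engine is a test harness, NOT a dose calculation algorithm: dose
at a point depends only on the water-equivalent depth along the beam axis,
with a trapezoidal percentage-depth-dose profile parameterised by the
rule-of-thumb electron ranges (R90 ~ E/4 cm, Rp ~ E/2 cm).  It exists so
that geometric bolus defects propagate into dose-metric differences with
the right sign and ordering; its absolute numbers carry no clinical
meaning.

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bolus import (
    BeamSpec,
    LayerTemplate,
    PARAFFIN_DENSITY_G_CM3,
    ABS_DENSITY_G_CM3,
    DEFAULT_SHEET_MM,
    SkinHeightMap,
    design_reference_bolus,
    slice_paraffin_layers,
    staircase_solid,
)
from .dose import DoseGrid, compare_plans, ptv_dose_metrics
from .geometry import (
    ContourSlice,
    ContourStack,
    Polygon2D,
    TriMesh,
    VoxelGrid,
    mesh_signed_volume,
    slice_mesh,
    voxelize_on_grid,
)
from .metrics import MatchResult, air_gap_fraction, matching_level
from .reconstruct import build_solid_from_contours

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "ElectronPDD",
    "Phantom",
    "make_phantom",
    "degrade_to_paraffin",
    "toy_depth_dose",
    "simulate",
    "SimulationReport",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Canthus-like phantom parameters.

    Defaults emulate the small-field clinical setting this pipeline targets:
    a 30 mm circular applicator, a Gaussian skin valley of 5 mm depth and
    6 mm width standing in for the canthus fold, a PTV reaching 10 mm under
    the skin (the clinical range being roughly 5.6-26 mm) and a 6 MeV beam.
    """

    aperture_mm: float = 30.0
    aperture_shape: str = "circle"  # circle | square
    relief_amplitude_mm: float = 5.0
    relief_width_mm: float = 6.0
    ptv_depth_mm: float = 10.0
    energy_mev: int = 6
    skin_step_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv_depth_mm <= 0:
            raise ValueError("PTV depth must be positive")
        if self.relief_amplitude_mm < 0:
            raise ValueError("relief amplitude must be non-negative")
        if self.aperture_mm <= self.relief_width_mm:
            raise ValueError("aperture must be larger than the relief width")
        if self.aperture_shape not in ("circle", "square"):
            raise ValueError(f"unknown aperture shape {self.aperture_shape!r}")


@dataclass(frozen=True)
class DegradationSpec:
    """Hand-fabrication error model for the paraffin bolus.

    ``shift_sd_mm`` is the standard deviation of the random lateral offset
    each 1.5 mm sheet acquires when pressed in place; ``air_gap_rate`` the
    fraction of interior voxels voided at sheet interfaces.  Both are free
    knobs, not calibrated claims; the defaults (1.0 mm, 5%) represent a
    plausible manual-layering error scale.
    """

    sheet_mm: float = DEFAULT_SHEET_MM
    shift_sd_mm: float = 1.0
    air_gap_rate: float = 0.05
    density_g_cm3: float = PARAFFIN_DENSITY_G_CM3

    def __post_init__(self) -> None:
        if min(self.sheet_mm, self.density_g_cm3) <= 0:
            raise ValueError("sheet thickness and density must be positive")
        if self.shift_sd_mm < 0 or not (0 <= self.air_gap_rate < 1):
            raise ValueError("shift sd must be >= 0 and air-gap rate in [0, 1)")


@dataclass(frozen=True)
class ElectronPDD:
    """Trapezoidal electron percentage-depth-dose in water (depths in mm).

    Linear build-up from the surface to ``d100``, unity plateau, then a
    linear fall-off crossing 90% at ``r90`` and reaching zero at the
    practical range ``rp``.
    """

    d100: float
    r90: float
    rp: float

    def __post_init__(self) -> None:
        if not (0 < self.d100 < self.r90 < self.rp):
            raise ValueError("need 0 < d100 < R90 < Rp")

    @classmethod
    def for_energy(cls, energy_mev: float) -> "ElectronPDD":
        r90 = 2.5 * energy_mev  # R90 ~ E/4 cm
        rp = 5.0 * energy_mev  # Rp ~ E/2 cm
        return cls(d100=0.6 * r90, r90=r90, rp=rp)

    @property
    def falloff_start(self) -> float:
        """Depth where the plateau ends so the fall-off passes 90% at R90."""
        return self.rp - (self.rp - self.r90) / 0.9

    def __call__(self, weq_depth_mm: np.ndarray) -> np.ndarray:
        w = np.asarray(weq_depth_mm, dtype=float)
        ds = self.falloff_start
        dose = np.where(
            w < self.d100,
            w / self.d100,
            np.where(
                w <= ds,
                1.0,
                np.clip((self.rp - w) / (self.rp - ds), 0.0, 1.0),
            ),
        )
        return np.clip(dose, 0.0, 1.0)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _aperture_polygon(spec: PhantomSpec) -> Polygon2D:
    if spec.aperture_shape == "square":
        h = spec.aperture_mm / 2.0
        return Polygon2D(np.array([[-h, -h], [h, -h], [h, h], [-h, h]]))
    r = spec.aperture_mm / 2.0
    th = np.linspace(0.0, 2.0 * np.pi, 65)[:-1]
    return Polygon2D(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    skin: SkinHeightMap
    beam: BeamSpec
    reference: TriMesh
    pdd: ElectronPDD

    def skin_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        s = self.spec
        r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
        return -s.relief_amplitude_mm * np.exp(-r2 / (2.0 * s.relief_width_mm**2))

    def ptv_mask(self, grid: VoxelGrid) -> np.ndarray:
        """PTV occupancy on a lattice: a skin-following plug under the valley."""
        xs, ys, zs = grid.center_coordinates()
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        surface = self.skin_height(gx, gy)
        r_ptv = self.spec.aperture_mm / 4.0
        lateral = (gx**2 + gy**2) <= r_ptv**2
        z = zs[None, None, :]
        depth_band = (z <= surface[:, :, None] - 0.5) & (
            z >= surface[:, :, None] - self.spec.ptv_depth_mm
        )
        return lateral[:, :, None] & depth_band


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build skin map, beam, and reference bolus for a phantom spec.

    The flat proximal plane is placed so that ~90% dose reaches the PTV
    depth through an unperturbed bolus: ``z_p = max(R90 - depth, 2 mm)``
    above the nominal skin plane z = 0.  Deterministic for a fixed spec.
    """
    margin = 4.0
    half = spec.aperture_mm / 2.0 + margin
    n = int(np.ceil(2 * half / spec.skin_step_mm)) + 1
    x = np.linspace(-half, half, n)
    y = x.copy()
    gx, gy = np.meshgrid(x, y, indexing="ij")
    z = -spec.relief_amplitude_mm * np.exp(
        -(gx**2 + gy**2) / (2.0 * spec.relief_width_mm**2)
    )
    skin = SkinHeightMap(x, y, z)
    pdd = ElectronPDD.for_energy(spec.energy_mev)
    z_p = max(pdd.r90 - spec.ptv_depth_mm, 2.0)
    beam = BeamSpec(
        aperture=_aperture_polygon(spec), energy_mev=spec.energy_mev, proximal_z=z_p
    )
    reference = design_reference_bolus(skin, beam)
    return Phantom(spec=spec, skin=skin, beam=beam, reference=reference, pdd=pdd)


# ---------------------------------------------------------------------------
# paraffin degradation
# ---------------------------------------------------------------------------


def degrade_to_paraffin(
    ref: TriMesh,
    spec: DegradationSpec,
    rng: np.random.Generator,
    grid_spacing_mm: float = 1.0,
) -> tuple[TriMesh, VoxelGrid]:
    """Emulate hand-layered paraffin fabrication of a reference bolus.

    The reference is sliced into sheets, each sheet template is shifted
    laterally by a normal error, and the shifted staircase is rebuilt as a
    solid.  The companion density grid carries the paraffin density with a
    configurable fraction of interior voxels voided in the voxel slabs
    nearest the sheet interfaces (the air gaps that joining sheets by hand
    produces).
    """
    templates = slice_paraffin_layers(ref, spec.sheet_mm)
    shifted: list[LayerTemplate] = []
    for t in templates:
        dx, dy = rng.normal(0.0, spec.shift_sd_mm, size=2)
        shifted.append(
            LayerTemplate(
                t.index, t.z_bottom, t.z_top, [p.translated(dx, dy) for p in t.polygons]
            )
        )
    mesh = staircase_solid(shifted)

    sp = np.full(3, float(grid_spacing_mm))
    lo = mesh.bounds[0] - sp
    dims = tuple(int(np.ceil(d)) for d in (mesh.bounds[1] + sp - lo) / sp)
    occ = voxelize_on_grid(mesh, lo, sp, dims)
    density = occ.values.astype(float) * spec.density_g_cm3

    if spec.air_gap_rate > 0:
        zs = occ.cell_centers_1d(2)
        interfaces = np.array([t.z_top for t in shifted[:-1]])
        near_iface = np.zeros(len(zs), dtype=bool)
        for zi in interfaces:
            near_iface |= np.abs(zs - zi) <= 0.5 * sp[2]
        interior = occ.values.astype(bool)
        candidates = np.argwhere(interior & near_iface[None, None, :])
        n_void = min(
            int(round(spec.air_gap_rate * interior.sum())), len(candidates)
        )
        if n_void:
            pick = rng.choice(len(candidates), size=n_void, replace=False)
            ix, iy, iz = candidates[pick].T
            density[ix, iy, iz] = 0.0
    return mesh, VoxelGrid(lo, sp, density, semantics="density")


# ---------------------------------------------------------------------------
# toy dose engine
# ---------------------------------------------------------------------------


def toy_depth_dose(
    media: VoxelGrid,
    pdd: ElectronPDD,
    axis: np.ndarray | tuple[float, float, float] = (0.0, 0.0, -1.0),
    dose_scale_gy: float = 60.0,
) -> VoxelGrid:
    """Depth-dose raster from a density grid (beam entering from +z).

    Dose at a voxel is ``dose_scale_gy * PDD(weq)`` where ``weq`` is the
    water-equivalent depth accumulated down the voxel column (density
    relative to water times path length, midpoint rule within the voxel).
    Only the ``-z`` axis is supported; pre-rotate grids for other beams.
    """
    if not np.allclose(np.asarray(axis, dtype=float), [0.0, 0.0, -1.0], atol=1e-12):
        raise ValueError("toy dose engine supports only a -z beam axis")
    if media.values.size == 0:  # pragma: no cover - VoxelGrid forbids this
        raise ValueError("beam axis does not intersect the grid")
    dz = float(media.spacing[2])
    rho_top_first = media.values[:, :, ::-1].astype(float)
    cum = np.cumsum(rho_top_first, axis=2) * dz
    weq_top_first = cum - 0.5 * rho_top_first * dz
    weq = weq_top_first[:, :, ::-1]
    dose = pdd(weq) * dose_scale_gy
    return VoxelGrid(media.origin.copy(), media.spacing.copy(), dose, semantics="dose")


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationReport:
    """Everything one seeded pipeline run measures."""

    seed: int
    ml_printed: MatchResult
    ml_paraffin: MatchResult
    dd_printed: dict[str, float]  # metric -> signed percent
    dd_paraffin: dict[str, float]
    air_gap_paraffin: float
    reference_volume_mm3: float
    printed_volume_mm3: float
    paraffin_volume_mm3: float

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ml_printed_pct": self.ml_printed.ml,
            "ml_paraffin_pct": self.ml_paraffin.ml,
            "dd_printed_pct": dict(self.dd_printed),
            "dd_paraffin_pct": dict(self.dd_paraffin),
            "air_gap_paraffin": self.air_gap_paraffin,
            "reference_volume_mm3": self.reference_volume_mm3,
            "printed_volume_mm3": self.printed_volume_mm3,
            "paraffin_volume_mm3": self.paraffin_volume_mm3,
        }


def _rebuild_printed(ref: TriMesh, ct_slice_mm: float = 2.0) -> TriMesh:
    """Emulate the print pipeline: contour the reference at CT-like slices
    and stitch the contours back into a solid."""
    z_lo, z_hi = ref.z_extent
    eps = 0.1
    mids = np.arange(z_lo + ct_slice_mm / 2.0, z_hi, ct_slice_mm)
    levels = np.unique(np.concatenate([[z_lo + eps], mids, [z_hi - eps]]))
    stack = slice_mesh(ref, levels)
    kept = [s for s in stack if not s.is_empty]
    return build_solid_from_contours(ContourStack(kept))


def _tissue_plus_bolus_density(
    phantom: Phantom,
    lattice: VoxelGrid,
    bolus_mesh: TriMesh | None,
    bolus_density: float,
    bolus_density_grid: VoxelGrid | None = None,
) -> VoxelGrid:
    """Density raster: water-equivalent tissue below the skin plus a bolus."""
    xs, ys, zs = lattice.center_coordinates()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    surface = phantom.skin_height(gx, gy)
    density = np.where(zs[None, None, :] < surface[:, :, None], 1.0, 0.0)
    if bolus_density_grid is not None:
        resampled = _resample_nearest(bolus_density_grid, lattice)
        density = np.maximum(density, resampled)
    elif bolus_mesh is not None:
        occ = voxelize_on_grid(
            bolus_mesh, lattice.origin, lattice.spacing, lattice.dims
        ).values.astype(bool)
        density = np.maximum(density, occ * bolus_density)
    return VoxelGrid(
        lattice.origin.copy(), lattice.spacing.copy(), density, semantics="density"
    )


def _resample_nearest(src: VoxelGrid, lattice: VoxelGrid) -> np.ndarray:
    """Nearest-neighbour resample of a grid onto another lattice (zeros outside)."""
    out = np.zeros(lattice.dims, dtype=float)
    coords = lattice.center_coordinates()
    idx = []
    inside = []
    for a in range(3):
        i = np.floor((coords[a] - src.origin[a]) / src.spacing[a]).astype(int)
        ok = (i >= 0) & (i < src.values.shape[a])
        idx.append(np.clip(i, 0, src.values.shape[a] - 1))
        inside.append(ok)
    mask = inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    gx, gy, gz = np.ix_(idx[0], idx[1], idx[2])
    out[mask] = src.values[gx, gy, gz][mask]
    return out


def _dose_lattice(phantom: Phantom, spacing: float) -> VoxelGrid:
    half = phantom.spec.aperture_mm / 2.0 + 4.0
    z_top = phantom.beam.proximal_z + 2.0
    z_bot = -phantom.spec.relief_amplitude_mm - phantom.spec.ptv_depth_mm - 6.0
    sp = np.full(3, float(spacing))
    origin = np.array([-half, -half, z_bot])
    dims = (
        int(np.ceil(2 * half / spacing)),
        int(np.ceil(2 * half / spacing)),
        int(np.ceil((z_top - z_bot) / spacing)),
    )
    return VoxelGrid(origin, sp, np.zeros(dims), semantics="occupancy")


def simulate(
    spec: PhantomSpec | None = None,
    degradation: DegradationSpec | None = None,
    seed: int | None = None,
    ml_spacing_mm: float = 0.5,
    dose_spacing_mm: float = 1.0,
    ct_slice_mm: float = 2.0,
) -> SimulationReport:
    """Run the whole pipeline on a synthetic phantom, seeded and deterministic.

    Designs the reference bolus, rebuilds it from its own CT-like contours
    (the print route), degrades it into a shifted, air-gapped paraffin
    staircase (the manual route), and reports Matching Level plus
    per-metric dose differences of both fabricated variants against the
    reference plan under the toy dose engine.
    """
    spec = spec or PhantomSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    degradation = degradation or DegradationSpec()
    rng = np.random.default_rng(spec.seed)

    phantom = make_phantom(spec)
    ref = phantom.reference
    printed = _rebuild_printed(ref, ct_slice_mm)
    paraffin_mesh, paraffin_density = degrade_to_paraffin(
        ref, degradation, rng, grid_spacing_mm=dose_spacing_mm
    )

    ml_printed = matching_level(ref, printed, spacing=ml_spacing_mm)
    ml_paraffin = matching_level(ref, paraffin_mesh, spacing=ml_spacing_mm)

    lattice = _dose_lattice(phantom, dose_spacing_mm)
    mask = phantom.ptv_mask(lattice)
    plans = {
        "reference": _tissue_plus_bolus_density(phantom, lattice, ref, 1.0),
        "printed": _tissue_plus_bolus_density(
            phantom, lattice, printed, ABS_DENSITY_G_CM3
        ),
        "paraffin": _tissue_plus_bolus_density(
            phantom, lattice, None, 0.0, bolus_density_grid=paraffin_density
        ),
    }
    metrics = {
        name: ptv_dose_metrics(DoseGrid(toy_depth_dose(grid, phantom.pdd), mask))
        for name, grid in plans.items()
    }
    keys = ("near_min", "mean", "near_max")
    dd_printed = {
        k: compare_plans(metrics["reference"], metrics["printed"])[k].delta_d
        for k in keys
    }
    dd_paraffin = {
        k: compare_plans(metrics["reference"], metrics["paraffin"])[k].delta_d
        for k in keys
    }
    gap = air_gap_fraction(paraffin_density, paraffin_mesh)
    return SimulationReport(
        seed=spec.seed,
        ml_printed=ml_printed,
        ml_paraffin=ml_paraffin,
        dd_printed=dd_printed,
        dd_paraffin=dd_paraffin,
        air_gap_paraffin=gap,
        reference_volume_mm3=mesh_signed_volume(ref),
        printed_volume_mm3=mesh_signed_volume(printed),
        paraffin_volume_mm3=mesh_signed_volume(paraffin_mesh),
    )
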