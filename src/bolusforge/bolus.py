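"""Reference bolus design and fabrication slicing.

A reference bolus for electron therapy is a water-equivalent solid whose
distal surface conforms to the patient's skin and whose flat proximal
surface is perpendicular to the beam central axis.  This module designs
such a solid against a skin height map, slices it into 1.5 mm paraffin
sheet templates (the manual fabrication route) or 100 um print layers (the
FDM route), and rebuilds the "as-built" staircase solid a stack of paraffin
sheets actually realizes.

The beam axis is fixed to ``-z`` here; arbitrary beam orientations are
handled by rigidly pre-rotating the inputs (``geometry.apply_transform``)
so that slicing stays horizontal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import Delaunay, QhullError

from .geometry import (
    ContourSlice,
    ContourStack,
    Polygon2D,
    TriMesh,
    cross_section,
    mesh_signed_volume,
    validate_mesh,
)
from .reconstruct import cap_polygon

__all__ = [
    "BeamSpec",
    "SkinHeightMap",
    "LayerTemplate",
    "ABS_DENSITY_G_CM3",
    "PARAFFIN_DENSITY_G_CM3",
    "DEFAULT_SHEET_MM",
    "DEFAULT_PRINT_LAYER_MM",
    "design_reference_bolus",
    "slice_paraffin_layers",
    "staircase_solid",
    "slice_print_layers",
    "export_templates",
]

#: density of the printed ABS copolymer, g/cm3 (close to soft tissue)
ABS_DENSITY_G_CM3 = 1.05
#: density of physical paraffin wax, g/cm3
PARAFFIN_DENSITY_G_CM3 = 0.9
#: thickness of a single paraffin sheet, mm
DEFAULT_SHEET_MM = 1.5
#: FDM print layer height, mm
DEFAULT_PRINT_LAYER_MM = 0.1


@dataclass(frozen=True)
class BeamSpec:
    """Electron beam geometry: central axis, nominal energy and aperture.

    ``aperture`` lies in the plane perpendicular to the axis; for the
    default ``-z`` axis its coordinates are plain (x, y) mm.
    ``proximal_z`` locates the flat proximal bolus surface along the axis.
    """

    aperture: Polygon2D
    energy_mev: int = 6
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    proximal_z: float = 10.0

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float).reshape(3)
        if not math.isclose(float(np.linalg.norm(a)), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("beam axis must be a unit vector")
        object.__setattr__(self, "axis", a)
        self.aperture.require_simple()


@dataclass(frozen=True)
class SkinHeightMap:
    """Skin surface elevation z(x, y) sampled on a regular grid (mm)."""

    x: np.ndarray  # (nx,) strictly increasing
    y: np.ndarray  # (ny,) strictly increasing
    z: np.ndarray  # (nx, ny)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if z.shape != (len(x), len(y)):
            raise ValueError("z must have shape (len(x), len(y))")
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
            raise ValueError("height map must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    @property
    def step(self) -> float:
        return float(min(np.min(np.diff(self.x)), np.min(np.diff(self.y))))

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator((self.x, self.y), self.z, method="linear")


@dataclass(frozen=True)
class LayerTemplate:
    """One fabrication layer: z band plus the cutting template polygon(s)."""

    index: int
    z_bottom: float
    z_top: float
    polygons: list[Polygon2D]

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("layer must have positive thickness")

    @property
    def thickness(self) -> float:
        return self.z_top - self.z_bottom

    @property
    def area(self) -> float:
        return sum(p.area for p in self.polygons)

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0


# ---------------------------------------------------------------------------
# reference bolus design
# ---------------------------------------------------------------------------


def _aperture_is_convex(p: Polygon2D, tol: float = 1e-9) -> bool:
    sp = p.shapely
    return sp.convex_hull.area <= sp.area * (1 + tol) + tol


def _terrain_triangulation(points: np.ndarray, n_ring: int) -> np.ndarray | None:
    """Triangulate boundary-ring + interior points; verify the ring edges.

    Returns None when the triangulation's boundary does not coincide with
    the aperture ring (which would break watertightness), e.g. because
    collinear ring points were bypassed by the convex hull.
    """
    ring_edges = {
        tuple(sorted((i, (i + 1) % n_ring))) for i in range(n_ring)
    }
    try:
        tri = Delaunay(points, qhull_options="Qbb Qc Qz")
    except QhullError:  # pragma: no cover - qhull pathologies
        return None
    simplices = tri.simplices
    edges = np.sort(
        np.concatenate(
            [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]]
        ),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = {tuple(int(v) for v in e) for e in uniq[counts == 1]}
    return simplices if boundary == ring_edges else None


def _refined_ring(ap: Polygon2D, n_target: int, bulge: float = 0.0) -> np.ndarray:
    """Ring of >= n_target vertices keeping the aperture corners.

    Extra vertices are spread over edges by largest remainder on length.
    With ``bulge > 0`` the edge-interior vertices are pushed outward along
    the edge normal by ``bulge * sin(pi t)`` (t the fractional position),
    which places them in strictly convex position so a convex-hull
    triangulation cannot bypass them; sub-micron bulges perturb the design
    volume far below the grid-resolution tolerance.
    """
    v = ap.vertices
    m = len(v)
    ring = np.vstack([v, v[:1]])
    seg = np.diff(ring, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    extra = max(n_target - m, 0)
    quota = extra * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    short = extra - base.sum()
    if short > 0:
        order = np.lexsort((np.arange(m), -(quota - base)))
        base[order[:short]] += 1
    pts = []
    for e in range(m):
        k = base[e]
        t = np.arange(k + 1) / (k + 1)
        p = ring[e] + t[:, None] * seg[e]
        if bulge > 0 and k > 0:
            normal = np.array([seg[e, 1], -seg[e, 0]]) / lengths[e]  # outward for CCW
            p = p + (bulge * np.sin(np.pi * t))[:, None] * normal
        pts.append(p)
    return np.vstack(pts)


def design_reference_bolus(skin: SkinHeightMap, beam: BeamSpec) -> TriMesh:
    """Design the reference bolus: skin-conforming below, flat on top.

    The solid is bounded below by the skin surface, above by the flat
    proximal plane ``z = beam.proximal_z`` (perpendicular to the beam
    central axis) and laterally by the beam aperture.  Its volume equals
    the aperture integral of (proximal plane - skin height) to within the
    height-map grid resolution.

    Only convex apertures are supported; the clinical field shapes this
    targets (circles and rectangles) all are.
    """
    if not np.allclose(beam.axis, [0.0, 0.0, -1.0], atol=1e-12):
        raise ValueError(
            "design assumes a -z beam axis; pre-rotate inputs with apply_transform"
        )
    ap = beam.aperture.ccw()
    if not _aperture_is_convex(ap):
        raise ValueError("only convex apertures are supported")
    step = skin.step
    n_ring = max(64, int(np.ceil(ap.perimeter / step)), len(ap.vertices))

    # interior sampling points: skin grid nodes comfortably inside the ring
    shrunk = ap.shapely.buffer(-0.35 * step)
    gx, gy = np.meshgrid(skin.x, skin.y, indexing="ij")
    inside = (
        shapely.contains_xy(shrunk, gx.ravel(), gy.ravel())
        if not shrunk.is_empty
        else np.zeros(gx.size, dtype=bool)
    )
    interior = np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])

    simplices = None
    for bulge in (0.0, 1e-6):
        ring = _refined_ring(ap, n_ring, bulge=bulge)
        n_ring_actual = len(ring)
        pts2d = np.vstack([ring, interior])
        simplices = _terrain_triangulation(pts2d, n_ring_actual)
        if simplices is not None:
            break
    if simplices is None:
        raise RuntimeError(
            "skin-surface triangulation boundary does not match the aperture ring"
        )
    n_ring = n_ring_actual

    interp = skin.interpolator()
    try:
        skin_z = interp(pts2d)
    except ValueError as exc:
        raise ValueError("skin height map does not cover the aperture") from exc
    z_p = float(beam.proximal_z)
    if z_p <= float(skin_z.max()):
        raise ValueError(
            "proximal plane intersects the skin surface (negative bolus thickness)"
        )
    # orient bottom faces downward (clockwise in plan view)
    a, b, c = (pts2d[simplices[:, k]] for k in range(3))
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    bottom = simplices.copy()
    flip = cross > 0
    bottom[flip] = bottom[flip][:, ::-1]

    n_pts = len(pts2d)
    verts = np.empty((n_pts + n_ring, 3))
    verts[:n_pts, :2] = pts2d
    verts[:n_pts, 2] = skin_z
    verts[n_pts:, :2] = ring
    verts[n_pts:, 2] = z_p

    faces = [bottom]
    # side wall between skin ring (indices 0..n_ring-1) and top ring
    for i in range(n_ring):
        j = (i + 1) % n_ring
        faces.append(np.array([[i, j, n_pts + j], [i, n_pts + j, n_pts + i]]))
    # flat top cap, upward normal
    top = cap_polygon(Polygon2D(ring)) + n_pts
    faces.append(top)

    mesh = TriMesh(verts, np.vstack(faces))
    rep = validate_mesh(mesh)
    if not rep.watertight or rep.signed_volume <= 0:
        raise RuntimeError("designed bolus failed the watertightness check")
    return mesh


# ---------------------------------------------------------------------------
# fabrication slicing
# ---------------------------------------------------------------------------

_CEIL_EPS = 1e-9


def _layer_count(height: float, thickness: float) -> int:
    return max(1, int(math.ceil(height / thickness - _CEIL_EPS)))


def slice_paraffin_layers(mesh: TriMesh, sheet: float = DEFAULT_SHEET_MM) -> list[LayerTemplate]:
    """Divide a bolus into horizontal paraffin-sheet layers.

    Layer count is ``ceil(height / sheet)``; the last layer keeps its true
    (possibly partial) thickness.  Each template polygon is the solid's
    cross-section at the layer's mid-height, which makes the staircase
    volume an unbiased estimate of the smooth volume.
    """
    if sheet <= 0:
        raise ValueError("sheet thickness must be positive")
    rep = validate_mesh(mesh)
    if not rep.watertight:
        raise ValueError("paraffin slicing requires a watertight mesh")
    z_lo, z_hi = mesh.z_extent
    height = z_hi - z_lo
    count = _layer_count(height, sheet)
    tm = mesh.to_trimesh()
    templates = []
    for i in range(count):
        zb = z_lo + i * sheet
        zt = min(zb + sheet, z_hi)
        polys = cross_section(tm, 0.5 * (zb + zt))
        templates.append(LayerTemplate(i, zb, zt, polys))
    return templates


def staircase_solid(templates: list[LayerTemplate]) -> TriMesh:
    """Union of vertical prisms, one per template layer (the as-built bolus).

    Consecutive prisms occupy disjoint z bands, so the signed volume equals
    ``sum(area_i * thickness_i)`` exactly; internal interface walls remain
    as coincident face pairs, which keeps every component closed.
    """
    live = [t for t in templates if not t.is_empty]
    if not live:
        raise ValueError("no non-empty templates to build from")
    all_v: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    base = 0
    for t in live:
        for poly in t.polygons:
            ring = poly.ccw()
            n = len(ring.vertices)
            v = np.empty((2 * n, 3))
            v[:n, :2] = ring.vertices
            v[:n, 2] = t.z_bottom
            v[n:, :2] = ring.vertices
            v[n:, 2] = t.z_top
            cap = cap_polygon(ring)
            f = [cap[:, ::-1], cap + n]
            side = []
            for i in range(n):
                j = (i + 1) % n
                side.append((i, j, n + j))
                side.append((i, n + j, n + i))
            f.append(np.asarray(side, dtype=np.int64))
            all_v.append(v)
            all_f.append(np.vstack(f) + base)
            base += 2 * n
    mesh = TriMesh(np.vstack(all_v), np.vstack(all_f))
    rep = validate_mesh(mesh)
    if not rep.watertight:
        raise RuntimeError("staircase solid failed the watertightness check")
    return mesh


def slice_print_layers(
    mesh: TriMesh, layer: float = DEFAULT_PRINT_LAYER_MM
) -> tuple[int, ContourStack]:
    """Divide a solid into FDM print layers (default 100 um).

    Returns the layer count ``ceil(height / layer)`` and the contour stack
    sampled at each layer's mid-height.
    """
    if layer <= 0:
        raise ValueError("print layer height must be positive")
    z_lo, z_hi = mesh.z_extent
    count = _layer_count(z_hi - z_lo, layer)
    tm = mesh.to_trimesh()
    slices = []
    for i in range(count):
        zb = z_lo + i * layer
        zt = min(zb + layer, z_hi)
        zm = 0.5 * (zb + zt)
        slices.append(ContourSlice(zm, cross_section(tm, zm)))
    return count, ContourStack(slices)


# ---------------------------------------------------------------------------
# template export
# ---------------------------------------------------------------------------


def _template_svg(t: LayerTemplate) -> str:
    pts = np.vstack([p.vertices for p in t.polygons]) if t.polygons else np.zeros((1, 2))
    lo = pts.min(axis=0) - 5.0
    hi = pts.max(axis=0) + 5.0
    w, h = hi - lo
    paths = []
    for p in t.polygons:
        d = "M " + " L ".join(f"{x:.4f},{y:.4f}" for x, y in p.vertices) + " Z"
        paths.append(
            f'<path d="{d}" fill="none" stroke="black" stroke-width="0.2"/>'
        )
    label = (
        f'<text x="{lo[0] + 1:.2f}" y="{lo[1] + 4:.2f}" font-size="3">'
        f"layer {t.index} ({t.z_bottom:.2f}-{t.z_top:.2f} mm)</text>"
    )
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.4f}mm" height="{h:.4f}mm" '
        f'viewBox="{lo[0]:.4f} {lo[1]:.4f} {w:.4f} {h:.4f}">\n'
        + "\n".join(paths)
        + "\n"
        + label
        + "\n</svg>\n"
    )


def export_templates(
    templates: list[LayerTemplate], out_dir: str | Path, format: str = "svg+csv"
) -> list[Path]:
    """Write per-layer cutting templates (true-scale SVG) and a CSV manifest."""
    parts = set(format.split("+"))
    if not parts or not parts.issubset({"svg", "csv"}):
        raise ValueError(f"unknown template format {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "svg" in parts:
        for t in templates:
            path = out_dir / f"layer_{t.index:03d}.svg"
            path.write_text(_template_svg(t))
            written.append(path)
    if "csv" in parts:
        path = out_dir / "templates.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["layer", "z_bottom", "z_top", "area_mm2"])
            for t in templates:
                w.writerow([t.index, f"{t.z_bottom:.6f}", f"{t.z_top:.6f}", f"{t.area:.6f}"])
        written.append(path)
    return written
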