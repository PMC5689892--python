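"""Core geometric types and operations.

Coordinates are right-handed and in millimetres throughout; ``z`` increases
toward the proximal (beam-source) side, matching the stacking direction of
CT slices, and the electron beam axis defaults to ``-z`` onto the skin.

The module provides the domain containers (polygons, contour stacks,
triangle meshes, voxel grids, rigid transforms), mesh measurement and
validation, deterministic cell-centre voxelization, plane slicing, and
least-squares landmark registration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import trimesh
from shapely.geometry import MultiPolygon, Polygon as _ShapelyPolygon


__all__ = [
    "Polygon2D",
    "ContourSlice",
    "ContourStack",
    "TriMesh",
    "VoxelGrid",
    "RigidTransform",
    "MeshValidation",
    "mesh_signed_volume",
    "validate_mesh",
    "voxelize",
    "voxelize_on_grid",
    "grid_volume",
    "slice_mesh",
    "cross_section",
    "fit_rigid_landmarks",
    "apply_transform",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Polygon2D:
    """A simple closed planar polygon (vertices in mm, closure implicit).

    The first vertex is not repeated at the end.  Signed area follows the
    shoelace convention: positive for counter-clockwise vertex order.
    """

    vertices: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)
        if abs(self.signed_area) <= 0.0:
            raise ValueError("polygon has zero area")

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.shapely.centroid.coords[0])

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def is_simple(self) -> bool:
        return bool(self.shapely.is_valid)

    def require_simple(self) -> "Polygon2D":
        if not self.is_simple():
            raise ValueError("polygon is self-intersecting")
        return self

    def reversed(self) -> "Polygon2D":
        return Polygon2D(self.vertices[::-1].copy())

    def ccw(self) -> "Polygon2D":
        return self if self.is_ccw else self.reversed()

    def translated(self, dx: float, dy: float) -> "Polygon2D":
        return Polygon2D(self.vertices + np.array([dx, dy]))


@dataclass(frozen=True)
class ContourSlice:
    """All contour polygons lying in the plane ``z = const``."""

    z: float
    polygons: list[Polygon2D]

    @property
    def area(self) -> float:
        return sum(p.area for p in self.polygons)

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0


@dataclass(frozen=True)
class ContourStack:
    """Planar contour slices at strictly increasing z (the TPS layer model)."""

    slices: list[ContourSlice]

    def __post_init__(self) -> None:
        zs = [s.z for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice z-levels must be strictly increasing")

    @property
    def z_levels(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)


@dataclass(frozen=True)
class TriMesh:
    """Triangle mesh: (n,3) float vertices in mm, (m,3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] corner coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def z_extent(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@dataclass
class VoxelGrid:
    """Axis-aligned scalar raster: occupancy (0/1), density (g/cm3) or dose (Gy).

    ``values`` is indexed ``[ix, iy, iz]``; the centre of cell ``(i, j, k)``
    is ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    origin: np.ndarray  # (3,) corner of the grid, mm
    spacing: np.ndarray  # (3,) cell edge lengths, mm
    values: np.ndarray  # (nx, ny, nz)
    semantics: str = "occupancy"  # occupancy | density | dose | mask

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with dims >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def cell_centers_1d(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.cell_centers_1d(a) for a in range(3))  # type: ignore[return-value]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> R @ x + t`` (no scaling, no reflection)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def residual_rms(self) -> float:
        return getattr(self, "_residual_rms", float("nan"))


# ---------------------------------------------------------------------------
# mesh measurement & validation
# ---------------------------------------------------------------------------


def mesh_signed_volume(mesh: TriMesh) -> float:
    """Signed volume in mm3 by the divergence theorem.

    Positive for a watertight mesh with outward-oriented (counter-clockwise
    seen from outside) faces; exactly negated when every face is reversed.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot measure an empty mesh")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


@dataclass(frozen=True)
class MeshValidation:
    watertight: bool
    boundary_edge_count: int
    orientation_consistent: bool
    self_intersecting: bool
    signed_volume: float


def _self_intersection_heuristic(mesh: TriMesh, n_planes: int = 5) -> bool:
    """Advisory check: sample a few z sections and look for non-simple rings.

    Catches gross self-intersections cheaply; a clean report is not a proof
    of global embeddedness.
    """
    try:
        tm = mesh.to_trimesh()
        zlo, zhi = tm.bounds[:, 2]
        if zhi <= zlo:
            return False
        for z in np.linspace(zlo, zhi, n_planes + 2)[1:-1]:
            sec = tm.section(plane_origin=[0, 0, z + _PLANE_EPS], plane_normal=[0, 0, 1])
            if sec is None:
                continue
            planar, _ = sec.to_2D()
            for ent in planar.entities:
                pts = planar.vertices[ent.points]
                if len(pts) >= 4:
                    ring = shapely.LinearRing(pts) if np.allclose(pts[0], pts[-1]) else shapely.LinearRing(np.vstack([pts, pts[:1]]))
                    if not ring.is_simple:
                        return True
    except Exception:  # pragma: no cover - advisory only
        return False
    return False


def validate_mesh(mesh: TriMesh) -> MeshValidation:
    """Report-only print-readiness check.

    Watertight means zero boundary edges and consistent winding (every
    undirected edge used exactly once in each direction).  Self-intersection
    is flagged with a warning but never fatal.
    """
    f = mesh.faces
    if len(f) == 0:
        return MeshValidation(False, 0, True, False, 0.0)
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = int(np.sum(counts == 1))
    # consistent winding: each doubly-used undirected edge appears once per direction
    consistent = True
    if np.any(counts > 2):
        consistent = False
    else:
        order = np.argsort(inverse, kind="stable")
        de = directed[order]
        inv = inverse[order]
        dup = inv[:-1] == inv[1:]
        if np.any(dup):
            first, second = de[:-1][dup], de[1:][dup]
            consistent = bool(np.all(np.all(first == second[:, ::-1], axis=1)))
    selfx = _self_intersection_heuristic(mesh)
    vol = mesh_signed_volume(mesh)
    watertight = boundary == 0 and consistent
    if selfx:
        warnings.warn("mesh has self-intersections; volumes may be unreliable")
    return MeshValidation(watertight, boundary, consistent, selfx, vol)


# ---------------------------------------------------------------------------
# plane slicing
# ---------------------------------------------------------------------------

_PLANE_EPS = 1e-6  # mm; fixed offset applied when a section plane is degenerate


def cross_section(mesh: TriMesh | trimesh.Trimesh, z: float) -> list[Polygon2D]:
    """Closed intersection polygons of the mesh with the plane ``z = const``.

    Returns an empty list when the plane misses the mesh.  A plane that
    grazes vertices/edges is retried at a fixed tiny offset so the result is
    deterministic.
    """
    tm = mesh.to_trimesh() if isinstance(mesh, TriMesh) else mesh
    for zq in (z, z + _PLANE_EPS, z - _PLANE_EPS):
        try:
            sec = tm.section(plane_origin=[0.0, 0.0, zq], plane_normal=[0.0, 0.0, 1.0])
        except Exception:
            sec = None
        if sec is None:
            lo, hi = tm.bounds[:, 2]
            if zq < lo or zq > hi:
                return []
            continue
        try:
            planar, to_3d = sec.to_2D()
            polys = planar.polygons_full
        except Exception:
            continue
        out: list[Polygon2D] = []
        for sp in polys:
            if sp is None or sp.is_empty:
                continue
            uv = np.asarray(sp.exterior.coords[:-1])
            pts = np.column_stack([uv, np.zeros(len(uv)), np.ones(len(uv))]) @ to_3d.T
            try:
                out.append(Polygon2D(pts[:, :2]).ccw())
            except ValueError:
                continue  # degenerate sliver
        if out:
            return out
    return []


def slice_mesh(mesh: TriMesh, z_values: Sequence[float]) -> ContourStack:
    """Section a watertight mesh at the given z planes into a contour stack.

    Planes that miss the mesh yield empty slices; z values are sorted
    ascending in the result.
    """
    tm = mesh.to_trimesh()
    zs = sorted(float(z) for z in z_values)
    slices = [ContourSlice(z, cross_section(tm, z)) for z in zs]
    return ContourStack(slices)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _slice_multipolygon(tm: trimesh.Trimesh, z: float):
    polys = cross_section(tm, z)
    if not polys:
        return None
    return shapely.union_all([p.shapely for p in polys])


def voxelize_on_grid(
    mesh: TriMesh,
    origin: np.ndarray,
    spacing: np.ndarray,
    dims: tuple[int, int, int],
) -> VoxelGrid:
    """Occupancy of ``mesh`` on an explicitly specified lattice.

    A cell is occupied iff its centre lies inside the mesh, decided by a
    parity test along axis-aligned rays realised as planar cross-sections
    plus point-in-polygon tests; a fixed tiny plane offset resolves
    vertex/edge grazing deterministically.
    """
    rep = validate_mesh(mesh)
    if not rep.watertight:
        raise ValueError("voxelization requires a watertight mesh")
    origin = np.asarray(origin, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    tm = mesh.to_trimesh()
    nx, ny, nz = dims
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing[0]
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing[1]
    zs = origin[2] + (np.arange(nz) + 0.5) * spacing[2]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    occ = np.zeros((nx, ny, nz), dtype=np.uint8)
    zlo, zhi = tm.bounds[:, 2]
    for k, z in enumerate(zs):
        if z < zlo or z > zhi:
            continue
        geom = _slice_multipolygon(tm, z)
        if geom is None or geom.is_empty:
            continue
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
        occ[:, :, k] = inside.reshape(nx, ny)
    return VoxelGrid(origin, spacing, occ, semantics="occupancy")


def voxelize(mesh: TriMesh, spacing: float = 0.5) -> VoxelGrid:
    """Occupancy grid covering the mesh bounding box with a one-cell margin.

    Default spacing 0.5 mm keeps the volume error well below the rounding
    of reported cm3 volumes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    b = mesh.bounds
    sp = np.full(3, float(spacing))
    origin = b[0] - sp
    dims = tuple(int(math.ceil(d)) for d in (b[1] + sp - origin) / sp)
    return voxelize_on_grid(mesh, origin, sp, dims)  # type: ignore[arg-type]


def grid_volume(grid: VoxelGrid) -> float:
    """Occupied-cell count times cell volume, in mm3."""
    return float(np.count_nonzero(grid.values)) * grid.cell_volume


# ---------------------------------------------------------------------------
# rigid landmark registration
# ---------------------------------------------------------------------------


def fit_rigid_landmarks(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` landmarks onto ``dst``.

    Kabsch/Umeyama solution without scaling: minimises
    ``sum_i |R @ src_i + t - dst_i|^2`` over proper rotations R and
    translations t.  Requires >= 3 non-collinear correspondences, as in
    three-point landmark registration of bolus CT images.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) != len(dst):
        raise ValueError("landmark sets must have equal counts")
    if len(src) < 3:
        raise ValueError("at least 3 landmark pairs are required")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise ValueError("landmarks are collinear; rotation is underdetermined")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    out = RigidTransform(R, t)
    res = out.apply(src) - dst
    object.__setattr__(out, "_residual_rms", float(np.sqrt(np.mean(np.sum(res**2, axis=1)))))
    return out


def apply_transform(mesh: TriMesh, t: RigidTransform) -> TriMesh:
    """Vertex-wise rigid motion; signed volume is invariant."""
    return TriMesh(t.apply(mesh.vertices), mesh.faces.copy())
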