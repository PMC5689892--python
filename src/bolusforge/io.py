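"""File I/O for meshes, voxel grids and landmarks.

STL (binary and ASCII, unit mm) through trimesh; voxel grids as
raw-encoding NRRD through SimpleITK; landmark points as ``name,x,y,z`` CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .geometry import TriMesh, VoxelGrid

__all__ = [
    "write_stl",
    "read_stl",
    "write_nrrd",
    "read_nrrd",
    "write_landmarks_csv",
    "read_landmarks_csv",
]


def write_stl(mesh: TriMesh, path: str | Path, binary: bool = True) -> Path:
    """Write a mesh as STL (binary little-endian by default, else ASCII)."""
    path = Path(path)
    data = mesh.to_trimesh().export(file_type="stl" if binary else "stl_ascii")
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)
    return path


def read_stl(path: str | Path) -> TriMesh:
    """Read an STL file (either dialect) without vertex merging surprises."""
    tm = trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(tm, trimesh.Trimesh):  # pragma: no cover - scene edge case
        tm = tm.to_mesh()
    # STL stores independent facets; merge exactly coincident vertices so the
    # watertightness census sees shared edges.
    tm.merge_vertices(digits_vertex=10)
    return TriMesh.from_trimesh(tm)


def write_nrrd(grid: VoxelGrid, path: str | Path) -> Path:
    """Serialize a voxel grid as uncompressed NRRD (diagonal space directions)."""
    path = Path(path)
    arr = np.ascontiguousarray(np.transpose(np.asarray(grid.values, dtype=np.float32), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    # NRRD origin convention: centre of the first voxel.
    first_center = grid.origin + 0.5 * grid.spacing
    img.SetOrigin(tuple(float(o) for o in first_center))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def read_nrrd(path: str | Path, semantics: str = "density") -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(float)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float) - 0.5 * spacing
    return VoxelGrid(origin, spacing, arr, semantics=semantics)


def write_landmarks_csv(path: str | Path, points: dict[str, np.ndarray]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name, p in points.items():
            w.writerow([name, *(format(float(c), ".6f") for c in p)])
    return path


def read_landmarks_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read ``name,x,y,z`` landmark rows (coordinates in mm)."""
    out: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError("landmark CSV must have columns name,x,y,z")
        for row in reader:
            out[row["name"]] = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
    if not out:
        raise ValueError("no landmarks in file")
    return out
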