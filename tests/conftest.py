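import numpy as np
import pytest
import trimesh

from bolusforge.geometry import ContourSlice, ContourStack, Polygon2D, TriMesh


def square(half: float, cx: float = 0.0, cy: float = 0.0) -> Polygon2D:
    return Polygon2D(
        np.array(
            [[cx - half, cy - half], [cx + half, cy - half],
             [cx + half, cy + half], [cx - half, cy + half]]
        )
    )


def ngon(radius: float, n: int = 32) -> Polygon2D:
    th = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    return Polygon2D(np.column_stack([radius * np.cos(th), radius * np.sin(th)]))


def box_mesh(extents, center=(0.0, 0.0, 0.0)) -> TriMesh:
    tm = trimesh.creation.box(
        extents=extents, transform=trimesh.transformations.translation_matrix(center)
    )
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def unit_cube() -> TriMesh:
    return box_mesh([1.0, 1.0, 1.0], center=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def icosphere10() -> TriMesh:
    tm = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def frustum_stack() -> ContourStack:
    """Square 2x2 tapering to 1x1 over 3 mm: volume (h/3)(A1+A2+sqrt(A1 A2)) = 7."""
    return ContourStack(
        [ContourSlice(0.0, [square(1.0)]), ContourSlice(3.0, [square(0.5)])]
    )


@pytest.fixture(scope="session")
def flat_skin():
    from bolusforge.bolus import SkinHeightMap

    x = np.arange(-20.0, 20.5, 1.0)
    return SkinHeightMap(x, x.copy(), np.zeros((len(x), len(x))))


@pytest.fixture(scope="session")
def valley_skin():
    """Gaussian skin valley, depth 5 mm, width 6 mm: the canthus stand-in."""
    from bolusforge.bolus import SkinHeightMap

    x = np.arange(-20.0, 20.5, 1.0)
    gx, gy = np.meshgrid(x, x, indexing="ij")
    z = -5.0 * np.exp(-(gx**2 + gy**2) / (2.0 * 6.0**2))
    return SkinHeightMap(x, x.copy(), z)
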