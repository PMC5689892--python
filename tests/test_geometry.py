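"""Mesh measurement, validation, voxelization, slicing and registration."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from bolusforge.geometry import (
    ContourStack,
    Polygon2D,
    RigidTransform,
    TriMesh,
    apply_transform,
    fit_rigid_landmarks,
    grid_volume,
    mesh_signed_volume,
    slice_mesh,
    validate_mesh,
    voxelize,
)
from conftest import box_mesh

SPHERE_VOL = 4.0 / 3.0 * np.pi * 10.0**3  # 4188.79 mm^3


class TestSignedVolume:
    def test_unit_cube_and_orientation_antisymmetry(self, unit_cube):
        assert mesh_signed_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)
        flipped = TriMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert mesh_signed_volume(flipped) == pytest.approx(-1.0, abs=1e-12)

    def test_icosphere_close_to_analytic(self, icosphere10):
        assert mesh_signed_volume(icosphere10) == pytest.approx(SPHERE_VOL, rel=5e-3)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            mesh_signed_volume(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))

    def test_rigid_invariance(self, icosphere10):
        """Signed volume is invariant under any rigid motion."""
        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        t = RigidTransform(rot, np.array([4.0, -7.0, 2.5]))
        v0 = mesh_signed_volume(icosphere10)
        v1 = mesh_signed_volume(apply_transform(icosphere10, t))
        assert v1 == pytest.approx(v0, rel=1e-9)


class TestValidateMesh:
    def test_closed_box_watertight(self, unit_cube):
        rep = validate_mesh(unit_cube)
        assert rep.watertight and rep.boundary_edge_count == 0
        assert rep.orientation_consistent

    def test_missing_quad_leaves_four_boundary_edges(self, unit_cube):
        # drop the two triangles of one box side
        open_box = TriMesh(unit_cube.vertices, unit_cube.faces[:-2])
        rep = validate_mesh(open_box)
        assert not rep.watertight
        assert rep.boundary_edge_count == 4

    def test_single_triangle(self):
        rep = validate_mesh(TriMesh(np.eye(3), np.array([[0, 1, 2]])))
        assert rep.boundary_edge_count == 3 and not rep.watertight


class TestVoxelize:
    def test_aligned_box_exact_cell_count(self):
        mesh = box_mesh([10, 10, 10], center=(5, 5, 5))
        grid = voxelize(mesh, spacing=1.0)
        assert int(np.count_nonzero(grid.values)) == 1000
        assert grid_volume(grid) == pytest.approx(1000.0)

    def test_sphere_volume_within_one_percent(self, icosphere10):
        grid = voxelize(icosphere10, spacing=0.5)
        assert grid_volume(grid) == pytest.approx(SPHERE_VOL, rel=0.01)

    def test_open_mesh_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            voxelize(TriMesh(unit_cube.vertices, unit_cube.faces[:-2]), 1.0)

    def test_empty_grid_volume_is_zero(self):
        from bolusforge.geometry import VoxelGrid

        g = VoxelGrid(np.zeros(3), np.ones(3), np.zeros((4, 4, 4)))
        assert grid_volume(g) == 0.0

    def test_convergence_to_mesh_volume(self, icosphere10):
        """Refining the lattice shrinks the volume error monotonically."""
        v_mesh = mesh_signed_volume(icosphere10)
        errs = [
            abs(grid_volume(voxelize(icosphere10, h)) - v_mesh) for h in (2.0, 1.0, 0.5)
        ]
        assert errs[0] > errs[1] > errs[2]


class TestSliceMesh:
    def test_cube_midheight_square(self):
        mesh = box_mesh([10, 10, 10], center=(0, 0, 5))
        stack = slice_mesh(mesh, [5.0])
        (s,) = stack.slices
        assert len(s.polygons) == 1
        assert s.area == pytest.approx(100.0, rel=1e-9)

    def test_cone_halfheight_area(self):
        tm = trimesh.creation.cone(radius=10.0, height=20.0, sections=64)
        mesh = TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))
        stack = slice_mesh(mesh, [10.0])
        # faceted cone: cross-section is the 64-gon at r/2, within 1% of pi (r/2)^2
        assert stack.slices[0].area == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_plane_above_mesh_gives_empty_slice(self, unit_cube):
        stack = slice_mesh(unit_cube, [5.0])
        assert stack.slices[0].is_empty

    def test_slice_areas_integrate_to_volume(self, icosphere10):
        """Trapezoid rule over dense slices recovers the volume of a convex solid."""
        zs = np.linspace(-10.0, 10.0, 101)
        stack = slice_mesh(icosphere10, zs)
        areas = np.array([s.area for s in stack.slices])
        vol = np.trapezoid(areas, zs)
        assert vol == pytest.approx(mesh_signed_volume(icosphere10), rel=0.01)


class TestRigidLandmarks:
    def test_identity_for_identical_triples(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        t = fit_rigid_landmarks(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_recovers_synthetic_rigid_motion(self, seed):
        """Forward-generate a rigid motion, recover it to sub-nm residual."""
        rng = np.random.default_rng(seed)
        src = rng.uniform(-50, 50, size=(5, 3))
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        trans = rng.uniform(-20, 20, size=3)
        dst = src @ rot.T + trans
        t = fit_rigid_landmarks(src, dst)
        assert t.residual_rms < 1e-9
        assert np.allclose(t.rotation, rot, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_landmarks(pts, pts + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rigid_landmarks(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_no_scaling_recovered(self):
        """A scaled correspondence must NOT be fit by scaling: residual stays."""
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        t = fit_rigid_landmarks(pts, 2.0 * pts)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert t.residual_rms > 1.0  # scale mismatch cannot be absorbed


class TestApplyTransform:
    def test_identity_and_translation(self, unit_cube):
        ident = RigidTransform.identity()
        assert np.allclose(apply_transform(unit_cube, ident).vertices, unit_cube.vertices)
        shift = RigidTransform(np.eye(3), np.array([3.0, -1.0, 2.0]))
        moved = apply_transform(unit_cube, shift)
        assert mesh_signed_volume(moved) == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_inverse(self, icosphere10):
        rot = Rotation.from_euler("zx", [77, -13], degrees=True).as_matrix()
        t = RigidTransform(rot, np.array([1.0, 2.0, 3.0]))
        back = apply_transform(apply_transform(icosphere10, t), t.inverse())
        assert np.allclose(back.vertices, icosphere10.vertices, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestPolygon2D:
    def test_signed_area_and_orientation(self):
        p = Polygon2D(np.array([[0.0, 0], [2, 0], [2, 1], [0, 1]]))
        assert p.signed_area == pytest.approx(2.0)
        assert p.is_ccw and not p.reversed().is_ccw
        assert p.perimeter == pytest.approx(6.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            Polygon2D(np.array([[0.0, 0], [1, 1], [2, 2]]))
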