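"""Contour ingestion, ring resampling, stitching and solid assembly."""

import json

import numpy as np
import pytest

from bolusforge.geometry import (
    ContourSlice,
    ContourStack,
    Polygon2D,
    mesh_signed_volume,
    slice_mesh,
    validate_mesh,
)
from bolusforge.reconstruct import (
    build_solid_from_contours,
    cap_polygon,
    read_contours_json,
    read_rtstruct_contours,
    refine_contour,
    resample_contour,
    stitch_band,
    write_contours_json,
)
from conftest import ngon, square


class TestContoursJson:
    def _write(self, tmp_path, doc):
        p = tmp_path / "c.json"
        p.write_text(json.dumps(doc))
        return p

    def test_two_slice_square_fixture(self, tmp_path):
        doc = {
            "schema": 1,
            "units": "mm",
            "slices": [
                {"z": 0.0, "polygons": [[[0, 0], [1, 0], [1, 1], [0, 1]]]},
                {"z": 2.0, "polygons": [[[0, 0], [1, 0], [1, 1], [0, 1]]]},
            ],
        }
        stack = read_contours_json(self._write(tmp_path, doc))
        assert len(stack) == 2
        assert stack.slices[0].polygons[0].is_ccw

    def test_unsorted_z_sorted_ascending(self, tmp_path):
        doc = {
            "slices": [
                {"z": 5.0, "polygons": [[[0, 0], [1, 0], [1, 1]]]},
                {"z": 1.0, "polygons": [[[0, 0], [1, 0], [1, 1]]]},
            ]
        }
        stack = read_contours_json(self._write(tmp_path, doc))
        assert list(stack.z_levels) == [1.0, 5.0]

    def test_self_intersecting_polygon_rejected_with_slice_index(self, tmp_path):
        bowtie = [[0, 0], [2, 2], [2, 0], [0, 2]]
        doc = {"slices": [{"z": 0.0, "polygons": [bowtie]},
                          {"z": 2.0, "polygons": [[[0, 0], [1, 0], [1, 1]]]}]}
        with pytest.raises(ValueError, match="slice 0"):
            read_contours_json(self._write(tmp_path, doc))

    def test_duplicate_z_rejected(self, tmp_path):
        tri = [[0, 0], [1, 0], [1, 1]]
        doc = {"slices": [{"z": 0.0, "polygons": [tri]}, {"z": 0.0, "polygons": [tri]}]}
        with pytest.raises(ValueError, match="duplicate"):
            read_contours_json(self._write(tmp_path, doc))

    def test_round_trip(self, tmp_path, frustum_stack):
        p = tmp_path / "f.json"
        write_contours_json(frustum_stack, p)
        back = read_contours_json(p)
        assert np.allclose(back.z_levels, frustum_stack.z_levels)


def _minimal_rtstruct(path, contours, geometric_type="CLOSED_PLANAR", roi="BOLUS"):
    """Write a synthetic minimal RTSTRUCT with one ROI holding the contours."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    fm.MediaStorageSOPInstanceUID = pydicom.uid.UID("1.2.3.4.5.6.7.8.9")
    fm.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=fm, preamble=b"\0" * 128)
    ds.SOPClassUID = fm.MediaStorageSOPClassUID
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    roi_ds = Dataset()
    roi_ds.ROINumber = 1
    roi_ds.ROIName = roi
    ds.StructureSetROISequence = [roi_ds]
    items = []
    for pts in contours:
        c = Dataset()
        c.ContourGeometricType = geometric_type
        c.NumberOfContourPoints = len(pts)
        c.ContourData = [f"{v:.4f}" for xyz in pts for v in xyz]
        items.append(c)
    rc = Dataset()
    rc.ReferencedROINumber = 1
    rc.ContourSequence = items
    ds.ROIContourSequence = [rc]
    ds.save_as(str(path), enforce_file_format=True)
    return path


class TestRTStruct:
    def _square_contours(self):
        sq = [(-5, -5), (5, -5), (5, 5), (-5, 5)]
        return [[(x, y, z) for x, y in sq] for z in (0.0, 2.0, 4.0)]

    def test_three_square_contours_round_trip(self, tmp_path):
        path = _minimal_rtstruct(tmp_path / "rs.dcm", self._square_contours())
        stack = read_rtstruct_contours(path, "BOLUS")
        assert len(stack) == 3
        assert stack.slices[1].polygons[0].area == pytest.approx(100.0)

    def test_absent_roi_name_rejected(self, tmp_path):
        path = _minimal_rtstruct(tmp_path / "rs.dcm", self._square_contours())
        with pytest.raises(ValueError, match="not found"):
            read_rtstruct_contours(path, "NOPE")

    def test_open_contour_type_rejected(self, tmp_path):
        path = _minimal_rtstruct(
            tmp_path / "rs.dcm", self._square_contours(), geometric_type="OPEN_PLANAR"
        )
        with pytest.raises(ValueError, match="CLOSED_PLANAR"):
            read_rtstruct_contours(path, "BOLUS")


class TestResample:
    def test_square_every_five_mm(self):
        p = resample_contour(square(5.0), 8)
        assert len(p.vertices) == 8
        d = np.diff(np.vstack([p.vertices, p.vertices[:1]]), axis=0)
        assert np.allclose(np.hypot(d[:, 0], d[:, 1]), 5.0)

    def test_circle_area_preserved_for_dense_sampling(self):
        c = ngon(10.0, 256)
        r = resample_contour(c, 64)
        assert r.area == pytest.approx(c.area, rel=0.01)
        assert r.perimeter == pytest.approx(c.perimeter, rel=1e-3)

    def test_orientation_preserved(self):
        p = resample_contour(square(5.0).reversed(), 16)
        assert not p.is_ccw

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            resample_contour(square(5.0), 2)

    def test_refine_keeps_geometry_exact(self):
        c = ngon(10.0, 32)
        r = refine_contour(c, 126)
        assert len(r.vertices) == 126
        assert r.area == pytest.approx(c.area, abs=1e-12)
        assert r.perimeter == pytest.approx(c.perimeter, abs=1e-12)


class TestStitchAndCap:
    def test_prism_band_with_caps_has_prism_volume(self):
        lower = resample_contour(square(1.0), 16)
        upper = resample_contour(square(1.0), 16)
        verts, faces, offset = stitch_band(lower, upper, 0.0, 2.0)
        assert offset == 0
        assert len(faces) == 32
        stack = ContourStack(
            [ContourSlice(0.0, [lower]), ContourSlice(2.0, [upper])]
        )
        assert mesh_signed_volume(build_solid_from_contours(stack)) == pytest.approx(8.0)

    def test_unequal_ring_counts_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            stitch_band(resample_contour(square(1.0), 8),
                        resample_contour(square(1.0), 16), 0.0, 1.0)

    def test_rotated_upper_ring_untwists(self):
        """A 90-degree-rotated identical square stitches to the same volume."""
        lower = square(1.0)
        upper = Polygon2D(np.roll(lower.vertices, 1, axis=0))
        stack = ContourStack([ContourSlice(0.0, [lower]), ContourSlice(2.0, [upper])])
        assert mesh_signed_volume(build_solid_from_contours(stack)) == pytest.approx(8.0)

    def test_convex_hexagon_caps_to_four_triangles(self):
        hexa = ngon(5.0, 6)
        faces = cap_polygon(hexa)
        assert len(faces) == 4

    def test_l_shape_area_conserved(self):
        ell = Polygon2D(np.array(
            [[0, 0], [4, 0], [4, 2], [2, 2], [2, 4], [0, 4]], dtype=float))
        faces = cap_polygon(ell)
        v = ell.vertices

        def tri_area(a, b, c):
            (x1, y1), (x2, y2) = v[b] - v[a], v[c] - v[a]
            return 0.5 * abs(x1 * y2 - y1 * x2)

        area = sum(tri_area(a, b, c) for a, b, c in faces)
        assert area == pytest.approx(ell.area, rel=1e-12)

    def test_non_simple_polygon_rejected(self):
        crossed = Polygon2D(np.array([[0, 0], [4, 0], [1, 3], [3, 3]], dtype=float))
        with pytest.raises(ValueError):
            cap_polygon(crossed)

    def test_degenerate_sliver_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            Polygon2D(np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float))


class TestBuildSolid:
    def test_two_square_box(self):
        stack = ContourStack(
            [ContourSlice(0.0, [square(0.5)]), ContourSlice(2.0, [square(0.5)])]
        )
        mesh = build_solid_from_contours(stack)
        assert validate_mesh(mesh).watertight
        assert mesh_signed_volume(mesh) == pytest.approx(2.0)

    def test_32gon_prism_identity_exact(self):
        c = ngon(10.0, 32)
        stack = ContourStack(
            [ContourSlice(z, [c]) for z in np.linspace(0.0, 20.0, 5)]
        )
        mesh = build_solid_from_contours(stack)
        assert mesh_signed_volume(mesh) == pytest.approx(c.area * 20.0, rel=1e-12)

    def test_frustum_formula_exact(self, frustum_stack):
        mesh = build_solid_from_contours(frustum_stack)
        assert mesh_signed_volume(mesh) == pytest.approx(7.0, rel=1e-12)

    def test_branching_stack_rejected(self):
        stack = ContourStack(
            [ContourSlice(0.0, [square(1.0), square(0.3, cx=5.0)]),
             ContourSlice(1.0, [square(1.0)])]
        )
        with pytest.raises(ValueError, match="branching"):
            build_solid_from_contours(stack)

    def test_output_always_watertight(self, frustum_stack):
        assert validate_mesh(build_solid_from_contours(frustum_stack)).watertight

    def test_volume_invariant_to_start_vertex_labeling(self):
        c = ngon(8.0, 48)
        rolled = Polygon2D(np.roll(c.vertices, 17, axis=0))
        s1 = ContourStack([ContourSlice(0.0, [c]), ContourSlice(5.0, [c])])
        s2 = ContourStack([ContourSlice(0.0, [c]), ContourSlice(5.0, [rolled])])
        v1 = mesh_signed_volume(build_solid_from_contours(s1))
        v2 = mesh_signed_volume(build_solid_from_contours(s2))
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_reslice_recovers_input_areas(self):
        """Rebuild then re-slice at the original levels: areas match closely."""
        c = ngon(10.0, 32)
        zs = np.linspace(0.0, 20.0, 5)
        stack = ContourStack([ContourSlice(z, [c]) for z in zs])
        mesh = build_solid_from_contours(stack)
        resliced = slice_mesh(mesh, zs[1:-1])
        for s in resliced:
            assert s.area == pytest.approx(c.area, rel=5e-3)

    def test_non_overlapping_contours_warn(self):
        stack = ContourStack(
            [ContourSlice(0.0, [square(1.0)]),
             ContourSlice(1.0, [square(1.0, cx=50.0)])]
        )
        with pytest.warns(UserWarning, match="overlap"):
            build_solid_from_contours(stack)
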