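"""Box geometry: VIA parsing, view merging, encoding, 3-D IOU."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from petbrainx import boxes
from petbrainx.boxes import Box2D, Box3D


def brute_force_iou(a: Box3D, b: Box3D, grid=12) -> float:
    """Voxel-membership enumeration oracle."""
    count_i = count_u = 0
    for x in range(grid):
        for y in range(grid):
            for z in range(grid):
                ina, inb = a.contains((x, y, z)), b.contains((x, y, z))
                count_i += ina and inb
                count_u += ina or inb
    return count_i / count_u


box_strategy = st.builds(
    Box3D,
    st.tuples(*[st.integers(0, 7)] * 3),
    st.tuples(*[st.integers(1, 4)] * 3),
)


class TestIou3d:
    def test_identity_is_one(self):
        b = Box3D((1, 2, 3), (4, 5, 6))
        assert boxes.iou3d(b, b) == 1.0

    def test_disjoint_is_zero(self):
        assert boxes.iou3d(Box3D((0, 0, 0), (2, 2, 2)), Box3D((5, 5, 5), (2, 2, 2))) == 0.0

    def test_half_overlap_example(self):
        a = Box3D((0, 0, 0), (2, 2, 2))
        b = Box3D((1, 0, 0), (2, 2, 2))
        assert boxes.iou3d(a, b) == pytest.approx(4 / 12)

    @given(box_strategy, box_strategy)
    def test_matches_voxel_enumeration_and_symmetric(self, a, b):
        iou = boxes.iou3d(a, b)
        assert iou == pytest.approx(brute_force_iou(a, b))
        assert iou == boxes.iou3d(b, a)
        assert 0.0 <= iou <= 1.0
        assert (iou == 1.0) == (a == b)

    def test_zero_size_box_rejected(self):
        with pytest.raises(ValueError):
            Box3D((0, 0, 0), (0, 2, 2))


class TestEncodeDecode:
    def test_full_grid_box_is_unit_vector(self):
        v = boxes.encode(Box3D((0, 0, 0), (50, 60, 70)), (50, 60, 70))
        assert np.allclose(v, [0, 0, 0, 1, 1, 1])

    def test_linear_scaling_example(self):
        v = boxes.encode(Box3D((25, 25, 25), (50, 50, 50)), (100, 100, 100))
        assert np.allclose(v, [0.25, 0.25, 0.25, 0.5, 0.5, 0.5])

    def test_roundtrip_on_random_boxes(self, rng):
        g = (50, 50, 50)
        for _ in range(100):
            mn = rng.integers(0, 40, 3)
            sz = rng.integers(1, 50 - mn.max(), 3)
            b = Box3D(tuple(int(v) for v in mn), tuple(int(v) for v in sz))
            assert boxes.decode(boxes.encode(b, g), g) == b

    def test_decode_clips_to_grid(self):
        b = boxes.decode(np.array([0.9, 0.9, 0.9, 0.4, 0.4, 0.4]), (10, 10, 10))
        assert b.max_corner == (10, 10, 10)

    def test_implausible_vector_rejected(self):
        with pytest.raises(ValueError, match="implausible"):
            boxes.decode(np.array([2.0, 0, 0, 0.5, 0.5, 0.5]), (10, 10, 10))


class TestMergeViews:
    def test_worked_example_z_union(self):
        ant = Box2D((10, 5), (30, 20), frame="anterior")   # x [10,40) z [5,25)
        lat = Box2D((12, 6), (26, 18), frame="lateral")    # y [12,38) z [6,24)
        merged = boxes.merge_views(ant, lat)
        assert merged == Box3D((10, 12, 5), (30, 26, 20))

    def test_identical_z_extent_preserved(self):
        ant = Box2D((1, 4), (5, 10), frame="anterior")
        lat = Box2D((2, 4), (6, 10), frame="lateral")
        m = boxes.merge_views(ant, lat)
        assert (m.min_corner[2], m.size[2]) == (4, 10)

    def test_reprojection_contains_originals(self, rng):
        for _ in range(50):
            a = Box2D(tuple(rng.integers(0, 20, 2)), tuple(rng.integers(1, 10, 2)),
                      frame="anterior")
            l = Box2D(tuple(rng.integers(0, 20, 2)), tuple(rng.integers(1, 10, 2)),
                      frame="lateral")
            m = boxes.merge_views(a, l)
            for orig, frame in ((a, "anterior"), (l, "lateral")):
                re = boxes.project(m, frame)
                assert re.min_corner[0] <= orig.min_corner[0]
                assert re.max_corner[0] >= orig.max_corner[0]
                assert re.min_corner[1] <= orig.min_corner[1]
                assert re.max_corner[1] >= orig.max_corner[1]

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            boxes.merge_views(Box2D((0, 0), (1, 1), "lateral"),
                              Box2D((0, 0), (1, 1), "anterior"))


class TestViaAnnotations:
    def _write(self, tmp_path, meta):
        p = tmp_path / "via.json"
        p.write_text(json.dumps({"_via_img_metadata": meta}))
        return p

    def test_rect_field_mapping_and_views(self, tmp_path):
        meta = {
            "scan1.png-1": {
                "filename": "scan1.png",
                "regions": [
                    {"shape_attributes": {"name": "rect", "x": 10, "y": 5,
                                          "width": 30, "height": 20},
                     "region_attributes": {"view": "anterior"}},
                    {"shape_attributes": {"name": "rect", "x": 12, "y": 6,
                                          "width": 26, "height": 18},
                     "region_attributes": {"view": "lateral"}},
                ],
            }
        }
        rec = boxes.read_via_annotations(self._write(tmp_path, meta))["scan1.png"]
        assert rec["whole_brain_present"] is True
        assert rec["anterior"] == Box2D((10, 5), (30, 20), "anterior")
        assert rec["lateral"] == Box2D((12, 6), (26, 18), "lateral")

    def test_zero_regions_flags_absent_brain(self, tmp_path):
        meta = {"scan2.png-1": {"filename": "scan2.png", "regions": []}}
        rec = boxes.read_via_annotations(self._write(tmp_path, meta))["scan2.png"]
        assert rec["whole_brain_present"] is False
        assert "anterior" not in rec

    def test_non_rect_region_rejected(self, tmp_path):
        meta = {
            "s.png-1": {
                "filename": "s.png",
                "regions": [{"shape_attributes": {"name": "circle", "cx": 1, "cy": 1,
                                                  "r": 5},
                             "region_attributes": {"view": "anterior"}}],
            }
        }
        with pytest.raises(ValueError, match="circle"):
            boxes.read_via_annotations(self._write(tmp_path, meta))

    def test_malformed_json_raises(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(json.JSONDecodeError):
            boxes.read_via_annotations(p)


def test_from_mask_box_is_tight(rng):
    mask = np.zeros((9, 9, 9), dtype=bool)
    pts = rng.integers(2, 7, (5, 3))
    mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    b = boxes.from_mask(mask)
    for ax in range(3):
        assert pts[:, ax].min() == b.min_corner[ax]
        assert pts[:, ax].max() == b.max_corner[ax] - 1
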