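"""The 13 traits on analytic shapes and rendered plants."""

import math

import numpy as np
import pytest
from skimage.measure import label
from skimage.transform import rotate

from shootpheno import geometry
from shootpheno.preprocess import PlantImage
from shootpheno.segmentation import BinaryMask, SegmentationResult, segment
from shootpheno.shape_traits import (
    TRAIT_NAMES,
    boundary_points,
    extract_traits,
    mask_points,
    rasterized_hull_count,
    trace_perimeter,
)


def _result_from_mask(mask, min_px=0):
    labels = label(mask, connectivity=2)
    sizes = [int(s) for s in np.bincount(labels.ravel())[1:]]
    return SegmentationResult(
        roi=BinaryMask(mask), labels=labels, component_sizes=sizes
    )


def _disk(radius=50):
    side = 2 * radius + 11
    yy, xx = np.mgrid[0:side, 0:side]
    c = side // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestAreas:
    def test_block_areas(self):
        m = np.zeros((6, 6), bool)
        m[1:3, 1:3] = True
        rec = extract_traits(_result_from_mask(m))
        assert rec.area == 4
        assert rec.object_sum_area == 4

    def test_empty_roi_all_missing(self):
        rec = extract_traits(_result_from_mask(np.zeros((5, 5), bool)))
        assert rec.area == 0 and rec.object_sum_area == 0
        assert math.isnan(rec.caliper_length)
        assert math.isnan(rec.roundness)

    def test_two_objects_union_vs_largest_mode(self):
        m = np.zeros((20, 20), bool)
        m[1:3, 1:3] = True  # 4 px
        m[10:13, 10:13] = True  # 9 px
        res = _result_from_mask(m)
        union = extract_traits(res, object_mode="union")
        largest = extract_traits(res, object_mode="largest")
        assert union.area == 13 and union.object_sum_area == 13
        assert largest.area == 9 and largest.object_sum_area == 13

    def test_disk_area_within_2pct(self):
        rec = extract_traits(_result_from_mask(_disk(50)))
        assert rec.area == pytest.approx(math.pi * 50**2, rel=0.02)


class TestBoundary:
    def test_3x3_block_boundary(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        bp = boundary_points(m)
        assert bp.shape[0] == 8
        rec = extract_traits(_result_from_mask(m))
        # caliper = 2*sqrt(2) over pixel centers
        assert rec.boundary_point_roundness == pytest.approx(8 / (math.pi * 2))

    def test_thin_line_all_boundary(self):
        m = np.zeros((5, 40), bool)
        m[2, 3:33] = True
        assert boundary_points(m).shape[0] == 30

    def test_disk_boundary_count(self):
        bp = boundary_points(_disk(50))
        assert bp.shape[0] == pytest.approx(2 * math.pi * 50, rel=0.15)

    def test_square_trace_perimeter(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        assert trace_perimeter(label(m)) == pytest.approx(36.0)

    def test_disk_trace_perimeter(self):
        assert trace_perimeter(label(_disk(50))) == pytest.approx(
            2 * math.pi * 50, rel=0.10
        )


class TestDerivedRatios:
    def test_disk_roundness_near_one(self):
        rec = extract_traits(_result_from_mask(_disk(50)))
        assert rec.roundness == pytest.approx(1.0, abs=0.05)

    def test_line_roundness(self):
        m = np.zeros((3, 102), bool)
        m[1, 1:101] = True
        rec = extract_traits(_result_from_mask(m))
        assert rec.roundness == pytest.approx(4 * 100 / (math.pi * 99**2), rel=1e-6)

    def test_disk_boundary_point_roundness(self):
        rec = extract_traits(_result_from_mask(_disk(50)))
        assert rec.boundary_point_roundness == pytest.approx(2 / 50, rel=0.20)

    def test_bpr_halves_under_dilation(self):
        small = extract_traits(_result_from_mask(_disk(30)))
        big = extract_traits(_result_from_mask(_disk(60)))
        ratio = big.boundary_point_roundness / small.boundary_point_roundness
        assert ratio == pytest.approx(0.5, rel=0.10)


class TestCircumferenceModes:
    def test_literal_mode_is_pi_times_mec_diameter(self):
        res = _result_from_mask(_disk(40))
        rec = extract_traits(res, circumference_mode="literal")
        assert rec.circumference == pytest.approx(
            math.pi * rec.min_enclosing_circle_diameter
        )
        assert rec.convex_hull_circumference == rec.circumference

    def test_hull_perimeter_not_above_object_perimeter(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = np.zeros((60, 60), bool)
            for _ in range(4):  # blobby non-convex union of rectangles
                r, c = rng.integers(5, 35, 2)
                h, w = rng.integers(8, 20, 2)
                m[r : r + h, c : c + w] = True
            rec = extract_traits(_result_from_mask(m))
            assert rec.convex_hull_circumference <= rec.circumference + 1e-9


class TestScalingAndRotation:
    def test_similarity_scaling(self):
        rec1 = extract_traits(_result_from_mask(_disk(30)))
        rec2 = extract_traits(_result_from_mask(_disk(60)))
        assert rec2.caliper_length / rec1.caliper_length == pytest.approx(2, rel=0.05)
        assert rec2.area / rec1.area == pytest.approx(4, rel=0.05)
        assert rec2.convex_hull_area / rec1.convex_hull_area == pytest.approx(
            4, rel=0.05
        )

    def test_rotation_robustness(self):
        rng = np.random.default_rng(5)
        m = np.zeros((160, 160), float)
        yy, xx = np.mgrid[0:160, 0:160]
        for _ in range(5):
            cy, cx = rng.uniform(60, 100, 2)
            a, b = rng.uniform(15, 30, 2)
            m[((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1] = 1.0
        m45 = rotate(m, 45, resize=True, order=0) > 0.5
        m = m > 0.5
        r0 = extract_traits(_result_from_mask(m))
        r45 = extract_traits(_result_from_mask(m45))
        for attr in ("caliper_length", "min_enclosing_circle_diameter"):
            assert getattr(r45, attr) == pytest.approx(
                getattr(r0, attr), rel=0.03
            )
        assert r45.convex_hull_area == pytest.approx(r0.convex_hull_area, rel=0.03)


class TestContainmentOnRenderedPlants:
    def test_containment_chain_and_jung(self, small_trial):
        _, ds = small_trial
        jung = 2 / math.sqrt(3)
        for key, image in ds.images.items():
            res = segment(image)
            if res.n_components == 0:
                continue
            obj = res.roi.pixels
            pts = mask_points(obj)
            hull = geometry.convex_hull(pts)
            rec = extract_traits(res, image)
            assert rec.area <= rasterized_hull_count(obj, hull) + 1e-9
            assert geometry.polygon_area(hull) <= rec.min_area_rectangle_area + 1e-6
            assert rec.caliper_length <= rec.min_enclosing_circle_diameter + 1e-6
            assert rec.min_enclosing_circle_diameter <= jung * rec.caliper_length + 1e-6
            assert rec.convex_hull_circumference <= rec.circumference + 1e-6
            assert 0 < rec.roundness <= 1.1

    def test_record_carries_metadata_and_all_traits(self, small_trial):
        _, ds = small_trial
        key, image = next(iter(ds.images.items()))
        rec = extract_traits(segment(image), image)
        d = rec.trait_values()
        assert set(d) == set(TRAIT_NAMES)
        assert rec.plant_id == key[0] and rec.view == key[2]
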