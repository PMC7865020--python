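"""Head-region geometry: grids, dedup, moments, orientation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stst

import schooltrack as st
from schooltrack.geometry import TWO_PI

from .conftest import rasterized_min_intersection


class TestSplitIntoGrids:
    def test_full_hd_two_way_split_matches_reference_layout(self):
        layout = st.split_into_grids((1920, 1080), 2, 30)
        spans = [(b.x_min, b.x_max) for b in layout.boxes]
        assert spans == [(0.0, 990.0), (930.0, 1920.0)]
        assert all(b.height == 1080 for b in layout.boxes)

    def test_single_split_is_identity(self):
        layout = st.split_into_grids((100, 100), 1, 0)
        assert len(layout.boxes) == 1
        b = layout.boxes[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (0, 0, 100, 100)

    def test_union_covers_frame_and_stripes_shared_by_pixel_enumeration(self):
        layout = st.split_into_grids((200, 100), 2, 10)
        cols = set()
        for b in layout.boxes:
            cols |= set(range(int(b.x_min), int(b.x_max)))
        assert cols == set(range(200))
        b0, b1 = layout.boxes
        shared = set(range(int(b0.x_min), int(b0.x_max))) & set(
            range(int(b1.x_min), int(b1.x_max))
        )
        # each grid extends overlap_px past the partition boundary
        assert len(shared) == 2 * 10

    def test_splits_along_longer_axis(self):
        layout = st.split_into_grids((100, 400), 2, 10)
        assert layout.boxes[0].y_max == 210  # split is vertical
        assert layout.boxes[0].width == 100

    def test_local_to_full_frame_mapping(self):
        layout = st.split_into_grids((1920, 1080), 2, 30)
        assert layout.to_full_frame(1, 5.0, 7.0) == (935.0, 7.0)

    def test_degenerate_overlap_rejected(self):
        with pytest.raises(ValueError):
            st.split_into_grids((100, 50), 2, 60)


class TestMinIntersection:
    def test_identical_boxes_score_one(self, box):
        a = box(0, 0, 10, 10)
        assert st.min_intersection(a, a) == 1.0

    def test_disjoint_boxes_score_zero(self, box):
        assert st.min_intersection(box(0, 0, 10, 10), box(20, 20, 30, 30)) == 0.0

    def test_half_overlap_matches_rasterization_oracle(self, box):
        a, b = box(0, 0, 10, 10), box(5, 0, 15, 10)
        assert st.min_intersection(a, b) == 0.5
        assert rasterized_min_intersection(a, b) == pytest.approx(0.5)

    @given(
        stst.tuples(
            *[stst.floats(min_value=0, max_value=50) for _ in range(4)],
            *[stst.floats(min_value=0, max_value=50) for _ in range(4)],
        )
    )
    def test_symmetric_and_bounded(self, coords):
        x0, y0, dx0, dy0, x1, y1, dx1, dy1 = coords
        try:
            a = st.BoundingBox(x0, y0, x0 + dx0 + 1e-3, y0 + dy0 + 1e-3)
            b = st.BoundingBox(x1, y1, x1 + dx1 + 1e-3, y1 + dy1 + 1e-3)
        except ValueError:
            return
        s = st.min_intersection(a, b)
        assert s == st.min_intersection(b, a)
        assert 0.0 <= s <= 1.0 + 1e-12


class TestDedup:
    def test_identical_boxes_collapse_to_one(self, box):
        a = box(0, 0, 10, 10)
        assert st.dedup_detections([a, box(0, 0, 10, 10)], 0.4) == [a]

    def test_disjoint_boxes_both_retained(self, box):
        boxes = [box(0, 0, 10, 10), box(30, 30, 40, 40)]
        assert st.dedup_detections(boxes, 0.4) == boxes

    def test_boundary_score_is_not_a_duplicate(self, box):
        # score exactly 0.4: strictly-greater comparison keeps both
        a, b = box(0, 0, 10, 10), box(6, 0, 16, 10)
        assert st.min_intersection(a, b) == pytest.approx(0.4)
        assert len(st.dedup_detections([a, b], 0.4)) == 2

    def test_larger_box_represents_the_cluster(self, box):
        small, large = box(0, 0, 10, 10), box(-1, -1, 11, 11)
        assert st.dedup_detections([small, large], 0.4) == [large]

    def test_chain_matches_greedy_by_area_oracle(self, box):
        boxes = [box(0, 0, 10, 10), box(4, 0, 14, 10), box(9, 0, 18.5, 10)]

        def oracle(bxs, thr):
            order = sorted(
                range(len(bxs)),
                key=lambda i: (-bxs[i].area, bxs[i].x_min, bxs[i].y_min),
            )
            kept = []
            for i in order:
                if all(st.min_intersection(bxs[i], bxs[j]) <= thr for j in kept):
                    kept.append(i)
            return [bxs[i] for i in sorted(kept)]

        got = st.dedup_detections(boxes, 0.4)
        assert got == oracle(boxes, 0.4)
        # every discarded box conflicts with a kept one
        for b in boxes:
            if b not in got:
                assert any(st.min_intersection(b, k) > 0.4 for k in got)

    def test_idempotent(self, rng, box):
        boxes = []
        for _ in range(25):
            x, y = rng.uniform(0, 50, 2)
            w, h = rng.uniform(2, 15, 2)
            boxes.append(st.BoundingBox(x, y, x + w, y + h))
        once = st.dedup_detections(boxes, 0.4)
        twice = st.dedup_detections(once, 0.4)
        assert once == twice
        for i, a in enumerate(once):
            for b in once[i + 1 :]:
                assert st.min_intersection(a, b) <= 0.4

    def test_empty_input(self):
        assert st.dedup_detections([], 0.4) == []


class TestCentroid:
    def test_uniform_square_centroid_is_geometric_center(self):
        p = st.IntensityPatch(np.ones((5, 5)))
        assert st.centroid_from_patch(p) == (2.0, 2.0)

    def test_point_mass(self):
        v = np.zeros((4, 6))
        v[3, 1] = 7.0
        assert st.centroid_from_patch(st.IntensityPatch(v)) == (1.0, 3.0)

    def test_3x3_ramp_matches_double_loop_oracle(self):
        v = np.arange(1.0, 10.0).reshape(3, 3)
        m00 = m10 = m01 = 0.0
        for j in range(3):  # y
            for i in range(3):  # x
                m00 += v[j, i]
                m10 += i * v[j, i]
                m01 += j * v[j, i]
        cx, cy = st.centroid_from_patch(st.IntensityPatch(v))
        assert cx == pytest.approx(m10 / m00)
        assert cy == pytest.approx(m01 / m00)

    def test_translation_equivariance(self, rng):
        v = rng.uniform(0, 1, size=(7, 9))
        c0 = st.centroid_from_patch(st.IntensityPatch(v, origin=(0, 0)))
        c1 = st.centroid_from_patch(st.IntensityPatch(v, origin=(12.5, -3.0)))
        assert c1[0] - c0[0] == pytest.approx(12.5)
        assert c1[1] - c0[1] == pytest.approx(-3.0)

    def test_all_zero_patch_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.centroid_from_patch(st.IntensityPatch(np.zeros((3, 3))))


class TestHeadOrientation:
    def test_vertical_up_in_image_coords(self):
        # tip below centroid in image coords (y down) -> +pi/2
        assert st.head_orientation((0, 0), (0, 1)) == pytest.approx(math.pi / 2)

    def test_vertical_down_wraps_to_three_half_pi(self):
        assert st.head_orientation((0, 0), (0, -1)) == pytest.approx(3 * math.pi / 2)

    def test_diagonal_quarter_pi(self):
        assert st.head_orientation((0, 0), (1, 1)) == pytest.approx(math.pi / 4)

    @pytest.mark.parametrize("k", range(16))
    def test_sixteen_direction_sweep_matches_atan2_oracle(self, k):
        ang = k * TWO_PI / 16
        tip = (math.cos(ang), math.sin(ang))
        got = st.head_orientation((0.0, 0.0), tip)
        expected = math.atan2(tip[1], tip[0]) % TWO_PI
        assert abs(got - expected) < 1e-12 or abs(got - expected - TWO_PI) < 1e-12

    def test_branch_formula_matches_atan2_oracle_randomized(self, rng):
        for _ in range(1000):
            c = rng.uniform(-10, 10, 2)
            p = rng.uniform(-10, 10, 2)
            if np.allclose(c, p):
                continue
            got = st.head_orientation(tuple(c), tuple(p))
            exp = math.atan2(p[1] - c[1], p[0] - c[0]) % TWO_PI
            assert min(abs(got - exp), TWO_PI - abs(got - exp)) < 1e-12

    def test_scale_invariance_along_ray(self, rng):
        c = (2.0, -1.0)
        p = (5.0, 3.0)
        far = (c[0] + 2 * (p[0] - c[0]), c[1] + 2 * (p[1] - c[1]))
        assert st.head_orientation(c, p) == st.head_orientation(c, far)

    def test_coincident_points_undefined(self):
        with pytest.raises(ValueError):
            st.head_orientation((1.0, 1.0), (1.0, 1.0))


def left_weighted_bar(n=21, heavy=1.0, light=0.25, split=7):
    v = np.zeros((5, n))
    v[2, :split] = heavy
    v[2, split:] = light
    return v


class TestTipFromPatch:
    def test_left_weighted_bar_tip_on_left(self):
        patch = st.IntensityPatch(left_weighted_bar())
        cx, cy = st.centroid_from_patch(patch)
        px, py = st.tip_from_patch(patch)
        assert px < cx
        assert py == pytest.approx(cy)

    def test_tip_distance_is_major_semi_axis(self):
        patch = st.IntensityPatch(left_weighted_bar())
        cx, cy = st.centroid_from_patch(patch)
        px, py = st.tip_from_patch(patch)
        v = patch.values
        i = np.arange(v.shape[1]) - cx
        mu20 = float((v * i[None, :] ** 2).sum() / v.sum())
        assert math.hypot(px - cx, py - cy) == pytest.approx(2 * math.sqrt(mu20))

    def test_rotation_equivariance_quarter_turn(self):
        v = left_weighted_bar()
        p0 = st.IntensityPatch(v)
        p90 = st.IntensityPatch(np.rot90(v, k=-1))  # x -> y in image coords
        t0 = st.tip_from_patch(p0)
        c0 = st.centroid_from_patch(p0)
        t90 = st.tip_from_patch(p90)
        c90 = st.centroid_from_patch(p90)
        a0 = st.head_orientation(c0, t0)
        a90 = st.head_orientation(c90, t90)
        assert (a90 - a0) % TWO_PI == pytest.approx(math.pi / 2, abs=1e-9)

    def test_isotropic_patch_rejected(self):
        n = 31
        y, x = np.mgrid[0:n, 0:n]
        r2 = (x - n // 2) ** 2 + (y - n // 2) ** 2
        disk = np.exp(-r2 / 40.0)
        with pytest.raises(ValueError, match="isotropic"):
            st.tip_from_patch(st.IntensityPatch(disk), isotropy_tol=1e-3)

    def test_skew_side_oracle_by_mass_split(self, rng):
        """The tip must land on the heavier-mass side of the major axis."""
        for _ in range(20):
            split = rng.integers(5, 9)
            heavy = rng.uniform(0.8, 1.5)
            patch = st.IntensityPatch(left_weighted_bar(heavy=heavy, split=split))
            cx, _ = st.centroid_from_patch(patch)
            v = patch.values
            i = np.arange(v.shape[1])
            mass_left = v[:, i < cx].sum()
            mass_right = v[:, i > cx].sum()
            px, _ = st.tip_from_patch(patch)
            if mass_left > mass_right:
                assert px < cx
            else:
                assert px > cx


class TestAgainstScikitImage:
    """Independent cross-check of the raw-moment arithmetic."""

    def test_centroid_matches_skimage_moments(self, rng):
        skimage = pytest.importorskip("skimage.measure")
        v = rng.uniform(0, 1, size=(11, 13))
        m = skimage.moments(v)
        # skimage indexes moments as m[order_row, order_col] = sum r^i c^j
        exp = (m[0, 1] / m[0, 0], m[1, 0] / m[0, 0])
        got = st.centroid_from_patch(st.IntensityPatch(v))
        assert got == pytest.approx(exp)
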