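"""Supervision construction: kernel sizing, masks, patch labels, cost."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lirnet import (
    PointAnnotationSet,
    annotation_cost,
    build_supervision_mask,
    kernel_size_from_distance,
    mean_two_nn_distance,
    patch_labels_from_points,
)
from lirnet.annotations import PatchLabelSet


def _pas(points, shape=(20, 20), image_id="img"):
    return PointAnnotationSet(image_id, np.asarray(points, float), shape)


class TestMeanTwoNN:
    def test_three_collinear_points(self):
        # points at 0, d, 2d on a line: per-point 2-NN means are
        # (d+2d)/2, (d+d)/2, (d+2d)/2
        d = 4.0
        pas = _pas([(5, 0), (5, d), (5, 2 * d)])
        expected = ((1.5 * d) + d + (1.5 * d)) / 3
        assert mean_two_nn_distance([pas]) == pytest.approx(expected)

    def test_unit_square_corners_vs_bruteforce(self):
        pts = [(0, 0), (0, 1), (1, 0), (1, 1)]
        pas = _pas(pts, shape=(4, 4))
        # brute force over all pairwise distances
        arr = np.asarray(pts, float)
        per_point = []
        for i in range(4):
            d = sorted(np.linalg.norm(arr - arr[i], axis=1)[np.arange(4) != i])
            per_point.append((d[0] + d[1]) / 2)
        assert mean_two_nn_distance([pas]) == pytest.approx(np.mean(per_point))

    def test_images_with_fewer_than_three_points_are_skipped(self):
        ok = _pas([(1, 1), (1, 5), (5, 1)])
        short = _pas([(2, 2), (3, 3)])
        assert mean_two_nn_distance([short, ok]) == mean_two_nn_distance([ok])

    def test_all_images_too_small_raises(self):
        with pytest.raises(ValueError):
            mean_two_nn_distance([_pas([(1, 1), (2, 2)])])


class TestKernelSize:
    @pytest.mark.parametrize(
        "distance,expected", [(15.22, 15), (10.34, 11), (12.56, 13)]
    )
    def test_benchmark_configurations(self, distance, expected):
        assert kernel_size_from_distance(distance) == expected

    def test_tie_on_even_integer_rounds_up(self):
        assert kernel_size_from_distance(14.0) == 15

    def test_small_distances_clamp_to_one(self):
        assert kernel_size_from_distance(0.3) == 1

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kernel_size_from_distance(0.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=200.0))
    def test_always_odd_and_nearest(self, d):
        k = kernel_size_from_distance(d)
        assert k % 2 == 1
        assert abs(k - d) <= 1.0 + 1e-9


class TestSupervisionMask:
    def test_center_point_object_and_background_sizes(self):
        pas = _pas([(4, 4)], shape=(9, 9))
        m = build_supervision_mask(pas, 3)
        assert m.n_objects == 1
        assert len(m.object_pixel_sets()[0]) == 9
        assert m.s_background == 81 - 9
        assert m.s_object == 9

    def test_corner_point_is_clipped_but_keeps_nominal_area(self):
        pas = _pas([(0, 0)], shape=(9, 9))
        m = build_supervision_mask(pas, 3)
        assert len(m.object_pixel_sets()[0]) == 4
        assert m.s_object == 9  # nominal kernel area, not the clipped size

    def test_overlapping_objects_vs_pixel_set_oracle(self):
        pas = _pas([(4, 4), (4, 5)], shape=(10, 10))
        m = build_supervision_mask(pas, 3)
        union = set.union(*m.object_pixel_sets())
        assert m.s_background == 100 - len(union)
        # background is exactly the complement
        bg = {(r, c) for r in range(10) for c in range(10)} - union
        assert {tuple(p) for p in np.argwhere(m.background)} == bg

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            build_supervision_mask(_pas([(3, 3)]), 4)

    def test_area_conservation_property(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 20, size=(7, 2))
        m = build_supervision_mask(_pas(pts), 5)
        union = set.union(*m.object_pixel_sets())
        assert m.s_background + len(union) == 20 * 20

    def test_label_image_exports(self):
        m = build_supervision_mask(_pas([(4, 4), (10, 10)]), 3)
        lab = m.to_label_image()
        assert set(np.unique(lab)) == {0, 1, 2}
        stack = m.to_label_stack()
        assert stack.shape == (2, 20, 20)
        assert stack[0].sum() == 9 and stack[1].sum() == 9


class TestPatchLabels:
    def test_empty_image_all_large_patches_zero(self):
        labels = patch_labels_from_points(_pas([], shape=(40, 40)), 20, 10)
        assert all(p.indicator == 0 and p.level == "large" for p in labels.patches)
        assert labels.n_patches == 4

    def test_single_point_labels_exactly_one_patch(self):
        labels = patch_labels_from_points(_pas([(5, 5)], shape=(40, 40)), 20, 10)
        inds = [p.indicator for p in labels.patches]
        assert sorted(inds) == [0, 0, 0, 1]

    def test_small_indicators_match_bruteforce_counting(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 40, size=(25, 2))
        pas = _pas(pts, shape=(40, 40))
        labels = patch_labels_from_points(pas, 20, 5, n_small_labels=None, seed=0)
        for p in labels.patches:
            r0, r1, c0, c1 = p.rect
            n = sum(1 for r, c in pts if r0 <= r < r1 and c0 <= c < c1)
            assert p.indicator == min(n, 2)

    def test_small_patches_only_inside_dense_large_patches(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 40, size=(30, 2))
        labels = patch_labels_from_points(_pas(pts, shape=(40, 40)), 20, 5, seed=1)
        dense = [p.rect for p in labels.patches if p.level == "large" and p.indicator == 2]
        for p in labels.patches:
            if p.level == "small":
                assert any(
                    R[0] <= p.rect[0] and p.rect[1] <= R[1] and R[2] <= p.rect[2] and p.rect[3] <= R[3]
                    for R in dense
                )

    def test_seeded_selection_is_deterministic_and_clamped(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 40, size=(30, 2))
        pas = _pas(pts, shape=(40, 40))
        a = patch_labels_from_points(pas, 20, 10, n_small_labels=3, seed=9)
        b = patch_labels_from_points(pas, 20, 10, n_small_labels=3, seed=9)
        assert a.patches == b.patches
        with pytest.warns(UserWarning):
            patch_labels_from_points(pas, 20, 10, n_small_labels=10_000, seed=9)

    def test_full_labeling_indicator_multiset_independent_of_seed(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 40, size=(30, 2))
        pas = _pas(pts, shape=(40, 40))
        a = patch_labels_from_points(pas, 20, 5, n_small_labels=None, seed=1)
        b = patch_labels_from_points(pas, 20, 5, n_small_labels=None, seed=2)
        assert sorted(p.indicator for p in a.patches) == sorted(p.indicator for p in b.patches)

    def test_drop_subdivided_large_removes_labeled_dense_patches(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 40, size=(30, 2))
        pas = _pas(pts, shape=(40, 40))
        kept = patch_labels_from_points(pas, 20, 5, n_small_labels=None, seed=0)
        dropped = patch_labels_from_points(
            pas, 20, 5, n_small_labels=None, seed=0, drop_subdivided_large=True
        )
        n_dense = sum(1 for p in kept.patches if p.level == "large" and p.indicator == 2)
        assert n_dense > 0
        assert dropped.n_patches == kept.n_patches - n_dense
        assert all(
            not (p.level == "large" and p.indicator == 2) for p in dropped.patches
        )

    def test_indivisible_grid_rejected(self):
        with pytest.raises(ValueError):
            patch_labels_from_points(_pas([(1, 1)]), 20, 7)

    def test_json_roundtrip(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 40, size=(12, 2))
        labels = patch_labels_from_points(_pas(pts, shape=(40, 40)), 20, 10, seed=0)
        back = PatchLabelSet.from_json(labels.to_json())
        assert back.patches == labels.patches
        assert back.image_shape == labels.image_shape


class TestAnnotationCost:
    def test_points_cost_counts_clicks(self):
        assert annotation_cost(_pas([(1, 1), (2, 2), (3, 3)])) == 3
        assert annotation_cost(_pas([], shape=(5, 5))) == 0

    def test_patch_cost_counts_labeled_patches(self):
        labels = patch_labels_from_points(_pas([], shape=(40, 40)), 20, 10)
        assert annotation_cost(labels) == 4

    def test_unknown_container_rejected(self):
        with pytest.raises(TypeError):
            annotation_cost([1, 2, 3])
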