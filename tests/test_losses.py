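"""Loss functions: closed-form examples, brute-force oracles, slope properties."""

import numpy as np
import pytest

from lirnet import (
    FSLLossParams,
    GaussianGTParams,
    PointAnnotationSet,
    WSLLossParams,
    build_supervision_mask,
    density_regularizer,
    fsl_loss_l1,
    fsl_loss_l2tanh,
    gaussian_density_map,
    patch_count,
    patch_labels_from_points,
    per_loss,
    truncate_count,
    wsl_patch_loss_l1,
    wsl_patch_loss_l2tanh,
    wsl_total_loss,
)


def _mask_two_objects(shape=(12, 12), kernel=3):
    h, w = shape
    pts = np.array([(h // 4, w // 4), (3 * h // 4 - 1, 3 * w // 4 - 1)], dtype=float)
    return build_supervision_mask(PointAnnotationSet("m", pts, shape), kernel)


def _ideal_density(mask):
    """Each object square sums to exactly 1, background exactly 0."""
    d = np.zeros(mask.image_shape)
    for r0, r1, c0, c1 in mask.object_rects:
        d[r0:r1, c0:c1] = 1.0 / ((r1 - r0) * (c1 - c0))
    return d


class TestFSLLosses:
    def test_ideal_map_gives_zero_for_both_forms(self):
        mask = _mask_two_objects()
        d = _ideal_density(mask)
        assert fsl_loss_l1(d, mask) == pytest.approx(0.0)
        assert fsl_loss_l2tanh(d, mask) == pytest.approx(0.0)

    def test_all_zero_map_values(self):
        mask = _mask_two_objects()
        z = np.zeros(mask.image_shape)
        assert fsl_loss_l2tanh(z, mask, FSLLossParams(lam=0.1)) == pytest.approx(0.1)
        assert fsl_loss_l1(z, mask) == pytest.approx(mask.n_objects)

    def test_single_background_pixel_contributes_directly(self):
        mask = _mask_two_objects()
        d = _ideal_density(mask)
        bg = np.argwhere(mask.background)[0]
        d[tuple(bg)] = 0.5
        assert fsl_loss_l1(d, mask) == pytest.approx(0.5)

    def test_uniform_map_matches_pixelwise_oracle(self):
        mask = _mask_two_objects(shape=(8, 8), kernel=3)
        c = 0.07
        d = np.full(mask.image_shape, c)
        lam = 0.1
        obj = np.mean([(9 * c - 1.0) ** 2 for _ in range(2)])
        # overlap-free objects here: background = 64 - 18 pixels
        bg_sum = c * mask.s_background
        expected = lam * obj + (1 - lam) * np.tanh(mask.s_object / mask.s_background * bg_sum)
        assert fsl_loss_l2tanh(d, mask, FSLLossParams(lam)) == pytest.approx(expected)
        expected_l1 = 2 * abs(9 * c - 1.0) + bg_sum
        assert fsl_loss_l1(d, mask) == pytest.approx(expected_l1)

    def test_object_permutation_invariance(self):
        mask = _mask_two_objects()
        rev = type(mask)(mask.image_shape, mask.object_rects[::-1], mask.kernel_size)
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 0.1, mask.image_shape)
        assert fsl_loss_l2tanh(d, mask) == pytest.approx(fsl_loss_l2tanh(d, rev))

    def test_l1_zero_iff_ideal(self):
        mask = _mask_two_objects()
        d = _ideal_density(mask)
        assert fsl_loss_l1(d, mask) == 0.0
        d[0, 0] += 1e-3  # a background pixel
        assert fsl_loss_l1(d, mask) > 0

    def test_gradients_match_finite_differences(self):
        mask = _mask_two_objects(shape=(8, 8))
        rng = np.random.default_rng(1)
        d = rng.uniform(0.01, 0.2, mask.image_shape)
        for fn in (
            lambda x, grad=False: fsl_loss_l1(x, mask, return_grad=grad),
            lambda x, grad=False: fsl_loss_l2tanh(x, mask, return_grad=grad),
        ):
            _, g = fn(d, grad=True)
            for idx in [(0, 0), (3, 3), (7, 5)]:
                dp, dm = d.copy(), d.copy()
                dp[idx] += 1e-6
                dm[idx] -= 1e-6
                num = (fn(dp) - fn(dm)) / 2e-6
                assert g[idx] == pytest.approx(num, abs=1e-5)


class TestGaussianGroundTruth:
    def test_integral_equals_point_count(self):
        pas = PointAnnotationSet("g", np.array([(5.0, 5.0), (10.0, 12.0), (1.0, 1.0)]), (16, 16))
        dm = gaussian_density_map(pas, GaussianGTParams(sigma=1.5))
        assert dm.total == pytest.approx(3.0, abs=1e-12)

    def test_empty_points_give_zero_map(self):
        pas = PointAnnotationSet("g", np.zeros((0, 2)), (8, 8))
        assert gaussian_density_map(pas, GaussianGTParams(sigma=1.0)).total == 0.0

    def test_single_point_matches_closed_form(self):
        pas = PointAnnotationSet("g", np.array([(4.0, 4.0)]), (9, 9))
        sig = 1.0
        dm = gaussian_density_map(pas, GaussianGTParams(sigma=sig))
        rr, cc = np.mgrid[0:9, 0:9]
        q = ((rr - 4.0) ** 2 + (cc - 4.0) ** 2) / (2 * sig**2)
        g = np.exp(-q)
        g[q > 4.5] = 0.0  # 3-sigma truncation
        assert np.allclose(dm.values, g / g.sum())

    def test_sigma_from_kernel(self):
        assert GaussianGTParams.from_kernel_size(10).sigma == 2.5


class TestPERLoss:
    def test_identical_maps_give_zero(self, rng):
        d = rng.uniform(0, 1, (6, 6))
        assert per_loss(d, d) == 0.0

    def test_unit_offset_gives_pixel_count(self):
        d = np.zeros((5, 7))
        assert per_loss(d + 1.0, d) == pytest.approx(35.0)

    def test_random_pair_matches_elementwise_oracle(self, rng):
        a, b = rng.uniform(0, 1, (6, 6)), rng.uniform(0, 1, (6, 6))
        expected = sum((a[i, j] - b[i, j]) ** 2 for i in range(6) for j in range(6))
        assert per_loss(a, b) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_loss(np.zeros((3, 3)), np.zeros((4, 4)))


class TestTruncation:
    @pytest.mark.parametrize(
        "c,expected", [(1.5, 1.5), (2.0, 2.0002), (10.0, 2.001), (0.0, 0.0)]
    )
    def test_branch_values(self, c, expected):
        assert truncate_count(c, WSLLossParams(gamma=1e-4)) == pytest.approx(expected)

    def test_monotone_with_slopes_one_and_gamma(self):
        params = WSLLossParams(gamma=1e-4)
        eps = 1e-5
        below = (truncate_count(1.0 + eps, params) - truncate_count(1.0, params)) / eps
        above = (truncate_count(3.0 + eps, params) - truncate_count(3.0, params)) / eps
        assert below == pytest.approx(1.0, rel=1e-6)
        assert above == pytest.approx(params.gamma, rel=1e-4)
        grid = [truncate_count(c, params) for c in np.linspace(0, 5, 100)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))


class TestPatchLosses:
    def test_patch_count_examples(self, rng):
        d = rng.uniform(0, 1, (10, 10))
        assert patch_count(np.zeros((10, 10)), (2, 5, 2, 5)) == 0.0
        assert patch_count(d, (0, 10, 0, 10)) == pytest.approx(d.sum())
        expected = sum(d[r, c] for r in range(2, 5) for c in range(3, 7))
        assert patch_count(d, (2, 5, 3, 7)) == pytest.approx(expected)
        with pytest.raises(ValueError):
            patch_count(d, (5, 12, 0, 3))

    def test_l2tanh_branches(self):
        assert wsl_patch_loss_l2tanh(0.0, 0) == 0.0
        assert wsl_patch_loss_l2tanh(1.0, 1) == 0.0
        assert wsl_patch_loss_l2tanh(2.5, 2) == pytest.approx(np.tanh(-0.5))

    def test_l1_branches_including_signed_dense_branch(self):
        assert wsl_patch_loss_l1(0.3, 0) == pytest.approx(0.3)
        assert wsl_patch_loss_l1(0.2, 1) == pytest.approx(0.8)
        assert wsl_patch_loss_l1(2.5, 2) == pytest.approx(-0.5)  # signed, negative

    @pytest.mark.parametrize("fn", [wsl_patch_loss_l1, wsl_patch_loss_l2tanh])
    def test_invalid_indicator_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, 3)

    def test_dense_branch_slope_is_minus_gamma_in_the_count(self):
        # through the truncation, d/dC [2 - T(C)] = -gamma for C >= 2
        params = WSLLossParams(gamma=1e-4)
        eps = 1e-4
        c = 4.0
        f = lambda x: wsl_patch_loss_l1(truncate_count(x, params), 2)
        slope = (f(c + eps) - f(c - eps)) / (2 * eps)
        assert slope == pytest.approx(-params.gamma, rel=1e-6)


class TestRegularizer:
    @pytest.mark.parametrize("dmax,expected", [(0.8, 0.0), (1.5, 0.5), (1.0, 0.0)])
    def test_boundary_cases(self, dmax, expected):
        d = np.zeros((4, 4))
        d[1, 2] = dmax
        assert density_regularizer(d) == pytest.approx(expected)


class TestWSLTotalLoss:
    def _labels(self, shape=(16, 16)):
        pts = np.array([(3.0, 3.0), (11.0, 4.0), (12.0, 12.0)])
        pas = PointAnnotationSet("w", pts, shape)
        return patch_labels_from_points(pas, 8, 4, n_small_labels=None, seed=0), pas

    def test_ideal_map_gives_zero_without_dense_patches(self):
        pas = PointAnnotationSet("w", np.array([(3.0, 3.0), (11.0, 11.0)]), (16, 16))
        labels = patch_labels_from_points(pas, 8, 4, seed=0)
        assert all(p.indicator < 2 for p in labels.patches)
        d = np.zeros((16, 16))
        d[3, 3] = 1.0
        d[11, 11] = 1.0
        assert wsl_total_loss(d, labels, form="l1") == pytest.approx(0.0)
        assert wsl_total_loss(d, labels, form="l2tanh") == pytest.approx(0.0)

    def test_all_zero_map_with_single_nucleus_patches(self):
        pas = PointAnnotationSet("w", np.array([(3.0, 3.0), (11.0, 11.0)]), (16, 16))
        labels = patch_labels_from_points(pas, 8, 4, seed=0)
        only_ones = type(labels)(
            labels.image_shape,
            labels.large_size,
            labels.small_size,
            [p for p in labels.patches if p.indicator == 1],
        )
        z = np.zeros((16, 16))
        assert wsl_total_loss(z, only_ones, form="l2tanh") == pytest.approx(1.0)

    def test_mixed_case_matches_term_by_term_oracle(self, rng):
        labels, _ = self._labels()
        params = WSLLossParams()
        d = rng.uniform(0, 0.3, (16, 16))
        d[2, 2] = 1.4  # activate the regularizer
        total = 0.0
        for p in labels.patches:
            r0, r1, c0, c1 = p.rect
            t = truncate_count(d[r0:r1, c0:c1].sum(), params)
            total += wsl_patch_loss_l1(t, p.indicator)
        expected = total / labels.n_patches + params.eta * (d.max() - 1.0)
        assert wsl_total_loss(d, labels, params, form="l1") == pytest.approx(expected)

    def test_empty_label_set_rejected(self):
        labels, _ = self._labels()
        empty = type(labels)(labels.image_shape, 8, 4, [])
        with pytest.raises(ValueError):
            wsl_total_loss(np.zeros((16, 16)), empty)

    def test_regularizer_bounds_the_dense_branch(self):
        """Without the max-density penalty the l1 dense-patch loss decreases
        without bound as the patch count grows; with it the total rises again."""
        pas = PointAnnotationSet("w", np.array([(3.0, 3.0), (4.0, 4.0), (3.0, 5.0)]), (8, 8))
        labels = patch_labels_from_points(pas, 8, 4, n_small_labels=0, seed=0)
        assert labels.patches[0].indicator == 2
        params_free = WSLLossParams(gamma=1e-4, eta=0.0)
        params_reg = WSLLossParams(gamma=1e-4, eta=1e-3)
        losses_free, losses_reg = [], []
        for scale in (1.0, 10.0, 1000.0):
            d = np.zeros((8, 8))
            d[2, 2] = scale
            losses_free.append(wsl_total_loss(d, labels, params_free, form="l1"))
            losses_reg.append(wsl_total_loss(d, labels, params_reg, form="l1"))
        assert losses_free[0] > losses_free[1] > losses_free[2]  # unbounded descent
        assert losses_reg[2] > losses_reg[1]  # penalty takes over

    def test_gradient_matches_finite_differences(self, rng):
        labels, _ = self._labels()
        d = rng.uniform(0.01, 0.4, (16, 16))
        for form in ("l1", "l2tanh"):
            _, g = wsl_total_loss(d, labels, form=form, return_grad=True)
            for idx in [(0, 0), (5, 9), (12, 12)]:
                dp, dm = d.copy(), d.copy()
                dp[idx] += 1e-7
                dm[idx] -= 1e-7
                num = (
                    wsl_total_loss(dp, labels, form=form) - wsl_total_loss(dm, labels, form=form)
                ) / 2e-7
                assert g[idx] == pytest.approx(num, abs=1e-5)
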