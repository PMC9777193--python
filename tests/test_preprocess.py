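"""Unit and property tests for the preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from ulcerseg import PreprocessConfig
from ulcerseg.exceptions import EmptyMaskError, ShapeMismatchError
from ulcerseg.preprocess import (
    ellipse_premask,
    masked_green,
    specular_reflection_mask,
    square_binarize,
    thin,
)

from conftest import rgb_canvas


def brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent exhaustive-search Otsu: maximize between-class variance."""
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    best_t, best_var = lo, -1.0
    for t in edges[1:-1]:
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            continue
        w1, w2 = low.size / values.size, high.size / values.size
        var = w1 * w2 * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestSpecularReflectionMask:
    def test_zero_blue_channel_keeps_everything(self, pp_cfg):
        img = rgb_canvas(value=(0.4, 0.4, 0.0))
        with pytest.warns(UserWarning, match="constant"):
            mask = specular_reflection_mask(img, pp_cfg)
        assert mask.all()

    def test_saturated_patch_is_excluded(self, pp_cfg):
        img = rgb_canvas(value=(0.5, 0.5, 0.5))
        img[20:25, 30:35] = 1.0
        mask = specular_reflection_mask(img, pp_cfg)
        assert not mask[20:25, 30:35].any()
        # far from the patch (beyond the closing radius) everything is kept
        assert mask[:10, :].all() and mask[:, :20].all()

    def test_reflection_recall_on_synthetic_scene(self, ulcer_scene, pp_cfg):
        mask = specular_reflection_mask(ulcer_scene.image, pp_cfg)
        refl = ulcer_scene.truth_reflections
        recall = (refl & ~mask).sum() / refl.sum()
        assert recall >= 0.95

    def test_idempotent_in_effect(self, ulcer_scene):
        """Masking reflections away then recomputing removes nothing new
        beyond closing-radius dilation effects.

        Tested in fixed-threshold mode: an adaptive (Otsu) threshold re-splits
        the remaining intensities after the reflections are gone, so the
        property is exact only for an absolute threshold.
        """
        cfg = PreprocessConfig(threshold_method="fixed", fixed_threshold=0.5)
        img = ulcer_scene.image
        mask1 = specular_reflection_mask(img, cfg)
        masked_img = img * mask1[..., None]
        mask2 = specular_reflection_mask(masked_img, cfg)
        removed2 = ~mask2
        allowance = ndi.binary_dilation(~mask1, iterations=2 * cfg.closing_radius)
        assert (removed2 & ~allowance).sum() == 0


class TestMaskedGreen:
    def test_identity_mask_returns_smoothed_green(self, pp_cfg):
        rng = np.random.default_rng(0)
        img = np.clip(rng.uniform(0, 1, (64, 64, 3)), 0, 1)
        mask = np.ones((64, 64), dtype=bool)
        out = masked_green(img, mask, pp_cfg)
        expected = ndi.gaussian_filter(img[..., 1], sigma=pp_cfg.gaussian_sigma)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_all_false_mask_zeroes_output(self, pp_cfg):
        img = rgb_canvas(value=(0.3, 0.8, 0.2))
        out = masked_green(img, np.zeros((64, 64), dtype=bool), pp_cfg)
        assert not out.any()

    def test_impulse_gives_sampled_gaussian_kernel(self):
        """Closed-form oracle: the response to a single bright pixel is the
        separable discrete Gaussian kernel centered on it."""
        cfg = PreprocessConfig(gaussian_sigma=2.0)
        img = np.zeros((65, 65, 3))
        img[32, 32, 1] = 1.0
        out = masked_green(img, np.ones((65, 65), dtype=bool), cfg)
        radius = int(4 * cfg.gaussian_sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * cfg.gaussian_sigma**2))
        k1 /= k1.sum()
        expected = np.zeros_like(out)
        expected[32 - radius : 32 + radius + 1, 32 - radius : 32 + radius + 1] = (
            np.outer(k1, k1)
        )
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_shape_mismatch_is_hard_error(self, pp_cfg):
        img = rgb_canvas()
        with pytest.raises(ShapeMismatchError):
            masked_green(img, np.ones((32, 64), dtype=bool), pp_cfg)

    def test_linear_in_image_for_fixed_mask(self, pp_cfg):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (64, 64, 3))
        mask = rng.uniform(size=(64, 64)) > 0.5
        alpha = 0.37
        out_scaled = masked_green(img * alpha, mask, pp_cfg)
        np.testing.assert_allclose(
            out_scaled, alpha * masked_green(img, mask, pp_cfg), atol=1e-12
        )


class TestSquareBinarize:
    def test_fixed_threshold_on_two_level_image(self):
        cfg = PreprocessConfig(threshold_method="fixed", fixed_threshold=0.5)
        gray = np.full((64, 64), 0.2)
        gray[10:20, 10:20] = 0.9
        mask = square_binarize(gray, cfg)
        # 0.9**2 = 0.81 > 0.5 while 0.2**2 = 0.04 is not
        assert mask[10:20, 10:20].all()
        assert mask.sum() == 100

    def test_all_zero_image_gives_empty_mask(self, pp_cfg):
        with pytest.warns(UserWarning, match="constant"):
            mask = square_binarize(np.zeros((64, 64)), pp_cfg)
        assert not mask.any()

    def test_otsu_on_squared_recovers_bright_disk(self, pp_cfg):
        rng = np.random.default_rng(7)
        gray = rng.uniform(0.0, 0.55, (96, 96))
        rr, cc = np.ogrid[:96, :96]
        disk = (rr - 48) ** 2 + (cc - 48) ** 2 <= 20**2
        gray[disk] = 0.95
        mask = square_binarize(gray, pp_cfg)
        iou = (mask & disk).sum() / (mask | disk).sum()
        assert iou >= 0.9
        # cross-check against an exhaustive-search Otsu oracle; thresholds may
        # differ by histogram discretization, so compare at bin resolution
        sq = gray**2
        t = brute_force_otsu(sq.ravel())
        bin_width = (sq.max() - sq.min()) / 256
        oracle_mask = sq > t
        disagree = mask ^ oracle_mask
        assert np.all(np.abs(sq[disagree] - t) <= 2 * bin_width)
        assert disagree.mean() < 0.005

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.95))
    def test_fixed_threshold_square_equivalence(self, seed, t):
        """Thresholding gray² at t is exactly thresholding gray at √t."""
        rng = np.random.default_rng(seed)
        gray = rng.uniform(0, 1, (32, 32))
        cfg = PreprocessConfig(threshold_method="fixed", fixed_threshold=t)
        np.testing.assert_array_equal(square_binarize(gray, cfg), gray > np.sqrt(t))


class TestEllipsePremask:
    def test_recovers_filled_ellipse_axes(self):
        cfg = PreprocessConfig(ellipse_dilation_factor=1.0)
        rr, cc = np.ogrid[:128, :128]
        truth = ((rr - 64) / 30) ** 2 + ((cc - 64) / 45) ** 2 <= 1.0
        out = ellipse_premask(truth, cfg)
        # recovered semi-axes within 1 px: compare half-extents
        rows = np.nonzero(out.any(axis=1))[0]
        cols = np.nonzero(out.any(axis=0))[0]
        assert abs((rows[-1] - rows[0]) / 2 - 30) <= 1.5
        assert abs((cols[-1] - cols[0]) / 2 - 45) <= 1.5

    def test_single_pixel_degenerates_to_disk(self, pp_cfg):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 40] = True
        out = ellipse_premask(mask, pp_cfg)
        rr, cc = np.ogrid[:64, :64]
        expected = (rr - 30) ** 2 + (cc - 40) ** 2 <= pp_cfg.closing_radius**2
        np.testing.assert_array_equal(out, expected)

    def test_two_blobs_get_one_covering_ellipse(self):
        cfg = PreprocessConfig(ellipse_dilation_factor=1.3)
        mask = np.zeros((96, 96), dtype=bool)
        rr, cc = np.ogrid[:96, :96]
        mask |= (rr - 30) ** 2 + (cc - 30) ** 2 <= 36
        mask |= (rr - 60) ** 2 + (cc - 66) ** 2 <= 36
        out = ellipse_premask(mask, cfg)
        # brute-force moment oracle: one ellipse from the union's moments
        rows, cols = np.nonzero(mask)
        r0, c0 = rows.mean(), cols.mean()
        sr = 2 * rows.std() * cfg.ellipse_dilation_factor
        sc = 2 * cols.std() * cfg.ellipse_dilation_factor
        expected = ((rr - r0) / sr) ** 2 + ((cc - c0) / sc) ** 2 <= 1.0
        np.testing.assert_array_equal(out, expected)
        assert out.sum() > 0 and out[int(r0), int(c0)]

    def test_empty_mask_is_an_error(self, pp_cfg):
        with pytest.raises(EmptyMaskError, match="no fluorescein"):
            ellipse_premask(np.zeros((64, 64), dtype=bool), pp_cfg)


class TestThin:
    def test_bar_thins_to_line(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:33, 10:30] = True
        out = thin(mask)
        assert out.sum() > 0
        assert (out.sum(axis=0) <= 1).all()  # at most one pixel per column

    def test_disk_skeleton_stays_near_center(self):
        rr, cc = np.ogrid[:64, :64]
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= 100
        out = thin(mask)
        rows, cols = np.nonzero(out)
        assert out.sum() >= 1
        assert np.hypot(rows - 32, cols - 32).max() <= 2.0

    def test_empty_stays_empty(self):
        assert not thin(np.zeros((64, 64), dtype=bool)).any()

    def test_subset_and_component_count(self):
        rng = np.random.default_rng(11)
        mask = ndi.binary_dilation(rng.uniform(size=(80, 80)) > 0.97, iterations=3)
        out = thin(mask)
        assert not (out & ~mask).any()
        n_in = ndi.label(mask, structure=np.ones((3, 3)))[1]
        n_out = ndi.label(out, structure=np.ones((3, 3)))[1]
        assert n_out <= n_in


def test_chain_is_deterministic(ulcer_scene, pp_cfg):
    img = ulcer_scene.image
    m1 = specular_reflection_mask(img, pp_cfg)
    m2 = specular_reflection_mask(img.copy(), pp_cfg)
    np.testing.assert_array_equal(m1, m2)
    g1 = masked_green(img, m1, pp_cfg)
    g2 = masked_green(img.copy(), m2, pp_cfg)
    np.testing.assert_array_equal(square_binarize(g1, pp_cfg), square_binarize(g2, pp_cfg))
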