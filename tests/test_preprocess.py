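"""Region-of-interest pipeline: blur, threshold, contours, crop, resize."""

import numpy as np
import pytest

from dhunet.config import BlurConfig, PreprocessConfig, SyntheticSpec
from dhunet.exceptions import ValidationError
from dhunet.preprocess import (CropBox, apply_crop, binarize, blur_gray,
                               compute_crop_box, extract_largest_contour,
                               gaussian_kernel, preprocess_sample, standardize)
from dhunet.synthetic import generate_sample


class TestBlurGray:
    @pytest.mark.parametrize("cfg", [BlurConfig(mode="median", kernel=3),
                                     BlurConfig(mode="gaussian", kernel=5)])
    def test_constant_image_stays_constant(self, cfg):
        img = np.full((16, 16, 3), 128, np.uint8)
        out = blur_gray(img, cfg)
        assert out.shape == (16, 16)
        assert (out == 128).all()

    def test_median_rejects_isolated_impulse(self):
        img = np.zeros((5, 5, 3), np.uint8)
        img[2, 2] = 255
        out = blur_gray(img, BlurConfig(mode="median", kernel=3))
        assert (out == 0).all()

    def test_gaussian_center_weight_matches_direct_summation(self):
        # independent discretisation of the 2-D Gaussian on the 5x5 support
        sigma = 1.0
        xs = np.arange(-2, 3, dtype=float)
        direct = np.array([[np.exp(-(x * x) / (2 * sigma ** 2)
                                   - (y * y) / (2 * sigma ** 2))
                            for x in xs] for y in xs])
        direct /= direct.sum()
        k = gaussian_kernel(5, sigma, sigma)
        assert k[2, 2] == pytest.approx(direct[2, 2], abs=1e-12)
        assert np.allclose(k, direct, atol=1e-12)
        assert k.sum() == pytest.approx(1.0)

    def test_luminance_weights(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 1] = 100  # pure green
        out = blur_gray(img, BlurConfig(mode="median", kernel=1))
        assert (out == 59).all()  # round(0.587 * 100)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            BlurConfig(mode="median", kernel=4)


class TestBinarize:
    def test_threshold_zero_all_positive(self):
        gray = np.full((4, 4), 3, np.uint8)
        assert (binarize(gray, 0) == 255).all()

    def test_boundary_convention_strict(self):
        gray = np.array([[200, 127]], np.uint8)
        out = binarize(gray, 127)
        assert out[0, 0] == 255 and out[0, 1] == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            binarize(np.zeros((2, 2), np.uint8), 300)

    def test_border_band_separation_on_synthetic_sample(self):
        spec = SyntheticSpec(seed=3, size=64, border_widths=(8, 8, 8, 8))
        img, _ = generate_sample(spec)
        binary = binarize(blur_gray(img, BlurConfig()), 10)
        assert (binary[:, :8] == 0).all() and (binary[:8, :] == 0).all()
        interior = binary[8:-8, 8:-8]
        assert (interior == 255).mean() >= 0.99


class TestContours:
    def test_empty_raster_gives_none(self):
        assert extract_largest_contour(np.zeros((10, 10), np.uint8)) is None

    def test_filled_rectangle(self):
        binary = np.zeros((40, 40), np.uint8)
        binary[5:15, 5:25] = 255  # 10 rows x 20 cols
        c = extract_largest_contour(binary)
        # pixel-centre shoelace area of a w x h block is (w-1)(h-1)
        assert c.area == pytest.approx(19 * 9)
        assert c.max_x == 24 and c.max_y == 14
        fx, fy = c.far_point
        assert 5 <= fx <= 24 and 5 <= fy <= 14

    def test_largest_of_two_regions_wins(self):
        binary = np.zeros((40, 40), np.uint8)
        binary[2:6, 2:6] = 255     # 4x4
        binary[20:28, 20:28] = 255  # 8x8
        c = extract_largest_contour(binary)
        assert c.vertices[:, 0].min() == 20 and c.max_x == 27


class TestCropBox:
    def test_bbox_of_rectangle(self):
        binary = np.zeros((100, 100), np.uint8)
        binary[5:15, 5:25] = 255
        c = extract_largest_contour(binary)
        box = compute_crop_box(c, (100, 100))
        assert (box.x0, box.y0, box.x1, box.y1) == (5, 5, 25, 15)

    def test_full_frame_identity(self):
        binary = np.full((30, 20), 255, np.uint8)
        box = compute_crop_box(extract_largest_contour(binary), (30, 20))
        assert (box.x0, box.y0, box.x1, box.y1) == (0, 0, 20, 30)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError):
            CropBox(5, 5, 5, 10)


class TestApplyCrop:
    def test_identity(self):
        img = np.arange(300, dtype=np.uint8).reshape(10, 10, 3)
        msk = (np.arange(100) % 2).astype(np.uint8).reshape(10, 10)
        out_i, out_m = apply_crop(img, msk, CropBox(0, 0, 10, 10))
        assert np.array_equal(out_i, img) and np.array_equal(out_m, msk)

    def test_window_arithmetic(self):
        img = np.zeros((100, 100, 3), np.uint8)
        msk = np.zeros((100, 100), np.uint8)
        out_i, out_m = apply_crop(img, msk, CropBox(5, 5, 25, 15))
        assert out_i.shape == (10, 20, 3) and out_m.shape == (10, 20)

    def test_foreground_count_preserved(self):
        img, msk = generate_sample(SyntheticSpec(seed=6, size=64))
        out_i, out_m = apply_crop(img, msk, CropBox(0, 0, 64, 64))
        assert out_m.sum() == msk.sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            apply_crop(np.zeros((5, 5, 3), np.uint8),
                       np.zeros((6, 5), np.uint8), CropBox(0, 0, 4, 4))


class TestStandardize:
    def test_same_size_is_scaling_only(self):
        img, msk = generate_sample(SyntheticSpec(seed=8, size=64))
        s = standardize(img, msk, target_size=64)
        assert np.allclose(s.image, img / 255.0, atol=1e-7)
        assert np.array_equal(s.mask, msk)

    def test_constant_mask_preserved(self):
        msk = np.ones((50, 50), np.uint8)
        img = np.zeros((50, 50, 3), np.uint8)
        s = standardize(img, msk, target_size=128)
        assert (s.mask == 1).all() and s.mask.shape == (128, 128)

    def test_disk_area_preserved_on_downscale(self):
        yy, xx = np.mgrid[:256, :256]
        msk = (((yy - 128) ** 2 + (xx - 128) ** 2) <= 60 ** 2).astype(np.uint8)
        img = np.zeros((256, 256, 3), np.uint8)
        s = standardize(img, msk, target_size=128)
        assert abs(s.mask.mean() - msk.mean()) <= 0.02

    def test_small_target_rejected(self):
        with pytest.raises(ValidationError):
            standardize(np.zeros((16, 16, 3), np.uint8),
                        np.zeros((16, 16), np.uint8), target_size=4)


class TestPreprocessSample:
    def test_borderless_sample_keeps_almost_full_frame(self):
        img, msk = generate_sample(SyntheticSpec(seed=12, size=128))
        s = preprocess_sample(img, msk)
        area = s.crop_box.width * s.crop_box.height
        assert area >= 0.95 * 128 * 128
        assert s.image.shape == (128, 128, 3) and s.mask.shape == (128, 128)

    @pytest.mark.parametrize("seed", range(6))
    def test_border_round_trip_recovers_interior(self, seed):
        widths_rng = np.random.default_rng(100 + seed)
        widths = tuple(int(w) for w in widths_rng.integers(0, 30, 4))
        img, msk = generate_sample(
            SyntheticSpec(seed=seed, size=128, border_widths=widths))
        s = preprocess_sample(img, msk)
        left, _, top, _ = widths
        assert (s.crop_box.x0, s.crop_box.y0) == (left, top)
        assert (s.crop_box.width, s.crop_box.height) == (128, 128)

    def test_no_black_band_survives(self):
        img, msk = generate_sample(
            SyntheticSpec(seed=2, size=128, border_widths=(15, 3, 0, 22)))
        s = preprocess_sample(img, msk)
        img8 = np.rint(s.image * 255)
        row_dark = (img8.max(axis=(1, 2)) == 0)
        col_dark = (img8.max(axis=(0, 2)) == 0)
        for dark in (row_dark, col_dark):
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, dark, 0])))
            assert not (runs >= 2).any() if runs.size else True

    def test_all_black_image_identity_crop(self):
        img = np.zeros((64, 64, 3), np.uint8)
        msk = np.zeros((64, 64), np.uint8)
        s = preprocess_sample(img, msk, PreprocessConfig(target_size=64))
        assert (s.crop_box.x0, s.crop_box.y0, s.crop_box.x1, s.crop_box.y1) == \
            (0, 0, 64, 64)
        assert s.image.shape == (64, 64, 3)

    def test_idempotence(self):
        img, msk = generate_sample(
            SyntheticSpec(seed=14, size=128, border_widths=(9, 0, 4, 7)))
        first = preprocess_sample(img, msk)
        img8 = np.clip(np.rint(first.image * 255), 0, 255).astype(np.uint8)
        second = preprocess_sample(img8, first.mask)
        assert np.array_equal(second.mask, first.mask)
        assert np.abs(second.image - first.image).max() <= 2 / 255

    def test_output_domain(self):
        img, msk = generate_sample(SyntheticSpec(seed=20, size=96))
        s = preprocess_sample(img, msk)
        assert 0.0 <= s.image.min() and s.image.max() <= 1.0
        assert set(np.unique(s.mask)) <= {0, 1}
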