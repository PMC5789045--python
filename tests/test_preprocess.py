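"""Intensity and geometry normalisation of raw 16-bit knee ROIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneekl.errors import DegenerateImageError, GeometryError
from kneekl.preprocess import (KneeROI, NormalizedImage, auto_exposure_gamma,
                               center_crop_mm, flip_if_left, gamma_correct,
                               truncate_and_rescale)


def _roi(pixels, spacing=0.5, side="right", **kw):
    return KneeROI(pixels=np.asarray(pixels), spacing_mm=spacing, side=side, **kw)


class TestTruncateAndRescale:
    def test_affine_endpoints_and_midpoint(self):
        # full-range percentiles make the affine map exact: 1000 -> 0,
        # 9000 -> 255, and the midpoint 5000 -> rint(127.5) = 128
        # (round-half-to-even)
        px = np.full((16, 16), 3000, dtype=np.uint16)
        px[0, 0], px[0, 1], px[0, 2] = 1000, 9000, 5000
        out = truncate_and_rescale(_roi(px), lo_pct=0, hi_pct=100)
        assert out.pixels[0, 0] == 0
        assert out.pixels[0, 1] == 255
        assert out.pixels[0, 2] == 128

    def test_matches_manual_formula(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 2**16, size=(64, 64)).astype(np.uint16)
        out = truncate_and_rescale(_roi(px), 5, 99)
        lo, hi = np.percentile(px, [5, 99])
        expect = np.clip(np.rint((np.clip(px, lo, hi) - lo) / (hi - lo) * 255),
                         0, 255)
        np.testing.assert_array_equal(out.pixels, expect.astype(np.uint8))

    def test_default_percentiles_are_5_and_99(self):
        import inspect

        sig = inspect.signature(truncate_and_rescale)
        assert sig.parameters["lo_pct"].default == 5.0
        assert sig.parameters["hi_pct"].default == 99.0

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            truncate_and_rescale(_roi(np.full((16, 16), 777, dtype=np.uint16)))

    def test_bad_percentile_order_raises(self):
        with pytest.raises(ValueError):
            truncate_and_rescale(_roi(np.arange(256).reshape(16, 16)), 99, 5)

    def test_idempotent_full_range(self):
        rng = np.random.default_rng(1)
        px = rng.integers(0, 2**16, size=(32, 32)).astype(np.uint16)
        once = truncate_and_rescale(_roi(px), 0, 100)
        twice = truncate_and_rescale(
            _roi(once.pixels.astype(np.uint16)), 0, 100)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_near_idempotent_inner_percentiles(self):
        # after the first pass >= 5% of mass saturates at each end, so a
        # second pass with the same percentiles moves pixels only by
        # quantisation-scale amounts
        rng = np.random.default_rng(2)
        px = rng.normal(10_000, 3_000, size=(128, 128)).clip(0, 65535)
        once = truncate_and_rescale(_roi(px.astype(np.uint16)), 5, 99)
        twice = truncate_and_rescale(_roi(once.pixels.astype(np.uint16)), 5, 99)
        assert np.abs(twice.pixels.astype(int) - once.pixels.astype(int)).max() <= 6


class TestFlipIfLeft:
    def test_right_knee_unchanged(self, random_roi):
        assert flip_if_left(random_roi) is random_roi

    def test_left_knee_mirrored_and_relabelled(self):
        px = np.zeros((16, 16), dtype=np.uint16)
        px[:, 0] = 40_000  # bright column at x = 0
        out = flip_if_left(_roi(px, side="left"))
        assert out.side == "right"
        assert (out.pixels[:, -1] == 40_000).all()
        assert (out.pixels[:, 0] == 0).all()

    def test_mirror_is_involution(self):
        rng = np.random.default_rng(4)
        px = rng.integers(0, 2**16, size=(16, 16)).astype(np.uint16)
        once = flip_if_left(_roi(px, side="left"))
        # relabel back to left so the mirror applies a second time
        again = flip_if_left(_roi(once.pixels, side="left"))
        np.testing.assert_array_equal(again.pixels, px)

    def test_margin_mask_flips_with_pixels(self):
        px = np.ones((16, 16), dtype=np.uint16)
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, 0] = True
        out = flip_if_left(_roi(px, side="left", margin_mask=mask))
        assert out.margin_mask[:, -1].all() and not out.margin_mask[:, 0].any()


class TestCenterCropMm:
    def test_140_to_130_mm(self, ramp_image):
        out = center_crop_mm(ramp_image, 130.0)
        assert out.pixels.shape == (260, 260)
        np.testing.assert_array_equal(out.pixels,
                                      ramp_image.pixels[10:270, 10:270])
        assert out.physical_size_mm == (130.0, 130.0)

    def test_odd_margin_goes_bottom_right(self):
        img = NormalizedImage((np.arange(81).reshape(9, 9) % 256).astype(np.uint8),
                              spacing_mm=1.0)
        out = center_crop_mm(img, 8.0)
        np.testing.assert_array_equal(out.pixels, img.pixels[0:8, 0:8])

    def test_identity_when_target_equals_size(self, ramp_image):
        out = center_crop_mm(ramp_image, 140.0)
        np.testing.assert_array_equal(out.pixels, ramp_image.pixels)

    def test_oversized_target_raises(self, ramp_image):
        with pytest.raises(GeometryError):
            center_crop_mm(ramp_image, 150.0)


class TestGammaCorrect:
    def test_identity_and_fixed_points(self, ramp_image):
        out = gamma_correct(ramp_image, 1.0)
        np.testing.assert_array_equal(out.pixels, ramp_image.pixels)
        extremes = NormalizedImage(np.array([[0, 255]] * 8, dtype=np.uint8), 1.0)
        for g in (0.3, 1.0, 4.0):
            out = gamma_correct(extremes, g)
            assert out.pixels[0, 0] == 0 and out.pixels[0, 1] == 255

    def test_hand_value(self):
        img = NormalizedImage(np.full((8, 8), 64, dtype=np.uint8), 1.0)
        assert gamma_correct(img, 2.0).pixels[0, 0] == 16  # 255*(64/255)^2

    def test_invalid_gamma_raises(self, ramp_image):
        with pytest.raises(ValueError):
            gamma_correct(ramp_image, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(gamma=st.floats(0.1, 5.0))
    def test_monotone_for_any_gamma(self, gamma):
        lut = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = gamma_correct(NormalizedImage(lut, 1.0), gamma).pixels.reshape(-1)
        assert (np.diff(out.astype(int)) >= 0).all()


class TestAutoExposureGamma:
    def test_in_band_unchanged(self):
        img = NormalizedImage(np.full((16, 16), 120, dtype=np.uint8), 1.0)
        assert auto_exposure_gamma(img) is img

    def test_dark_image_brightened(self):
        img = NormalizedImage(np.full((16, 16), 20, dtype=np.uint8), 1.0)
        out = auto_exposure_gamma(img)
        assert out.pixels.mean() > img.pixels.mean()

    def test_bright_image_darkened(self):
        img = NormalizedImage(np.full((16, 16), 240, dtype=np.uint8), 1.0)
        out = auto_exposure_gamma(img)
        assert out.pixels.mean() < img.pixels.mean()


class TestRoiValidation:
    def test_rejects_bad_inputs(self):
        ok = np.ones((16, 16), dtype=np.uint16)
        with pytest.raises(ValueError):
            KneeROI(pixels=np.ones(16, dtype=np.uint16), spacing_mm=0.5, side="right")
        with pytest.raises(ValueError):
            KneeROI(pixels=ok, spacing_mm=0.0, side="right")
        with pytest.raises(ValueError):
            KneeROI(pixels=ok, spacing_mm=0.5, side="up")
        with pytest.raises(ValueError):
            KneeROI(pixels=ok, spacing_mm=0.5, side="left", kl_grade=7)
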