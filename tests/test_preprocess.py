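"""Preprocessing chain: gamma, rolling-ball background subtraction, CLAHE,
pixel-size normalization, quadrant splitting, and full-chain invariants."""

from __future__ import annotations

import numpy as np
import pytest

from leukofrac.core import Mosaic
from leukofrac.preprocess import (
    PreprocessConfig,
    apply_clahe,
    gamma_correct,
    normalize_pixel_size,
    preprocess_mosaic,
    split_mosaic,
    subtract_background,
)


def _mosaic(pixels, pixel_size=0.5):
    return Mosaic(np.asarray(pixels, dtype=np.float32), pixel_size=pixel_size)


class TestGammaCorrect:
    def test_fixed_points_and_power_law(self):
        m = _mosaic(np.array([[[0.0, 1.0], [0.5, 0.25]]]).reshape(1, 2, 2))
        out = gamma_correct(m, 0.7).pixels
        assert out[0, 0, 0] == 0.0
        assert out[0, 0, 1] == 1.0
        assert out[0, 1, 0] == pytest.approx(0.5**0.7, abs=1e-5)  # 0.61557
        assert out[0, 1, 1] == pytest.approx(0.25**0.7, abs=1e-5)

    def test_gamma_one_is_identity(self, flat_mosaic):
        np.testing.assert_array_equal(
            gamma_correct(flat_mosaic, 1.0).pixels, flat_mosaic.pixels
        )

    def test_nonpositive_gamma_rejected(self, flat_mosaic):
        with pytest.raises(ValueError):
            gamma_correct(flat_mosaic, 0.0)


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self, flat_mosaic):
        out = subtract_background(flat_mosaic, radius_um=25.0)
        assert float(np.abs(out.pixels).max()) < 1e-3

    def test_small_disc_preserved_plane_removed(self):
        h = w = 256
        yy, xx = np.mgrid[0:h, 0:w]
        disc = (np.hypot(yy - 128, xx - 128) <= 10).astype(np.float32) * 0.5
        img = disc + 0.3  # constant plane
        m = _mosaic(img[:, :, None])
        out = subtract_background(m, radius_um=25.0).pixels[:, :, 0]
        peak = out[128, 128]
        assert peak == pytest.approx(0.5, rel=0.05)
        assert abs(float(out[20, 20])) < 0.02  # plane removed

    def test_output_non_negative(self, artifact_mosaic):
        out = subtract_background(artifact_mosaic.image, radius_um=25.0)
        assert float(out.pixels.min()) >= 0.0

    def test_radius_below_two_pixels_rejected(self, flat_mosaic):
        with pytest.raises(ValueError):
            subtract_background(flat_mosaic, radius_um=0.5)


class TestClahe:
    def test_constant_image_unchanged(self, flat_mosaic):
        out = apply_clahe(flat_mosaic, clip=0.01, tile=64)
        np.testing.assert_allclose(out.pixels, flat_mosaic.pixels, atol=1e-6)

    def test_contrast_non_decreasing_on_cells(self, mixed_mosaic):
        img = mixed_mosaic.image
        mask = mixed_mosaic.cell_union_mask()
        out = apply_clahe(img, clip=0.01, tile=64)
        for c in range(2):
            before = img.pixels[:, :, c][mask].mean() - img.pixels[:, :, c][~mask].mean()
            after = out.pixels[:, :, c][mask].mean() - out.pixels[:, :, c][~mask].mean()
            assert after >= before - 1e-6

    def test_output_in_unit_range(self, mixed_mosaic):
        out = apply_clahe(mixed_mosaic.image)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_tile_larger_than_image_rejected(self, flat_mosaic):
        with pytest.raises(ValueError):
            apply_clahe(flat_mosaic, tile=512)


class TestNormalizePixelSize:
    def test_integer_downscale(self):
        m = _mosaic(np.random.default_rng(0).random((1000, 1000, 2)), pixel_size=0.25)
        out = normalize_pixel_size(m, 0.5)
        assert out.pixels.shape == (500, 500, 2)
        assert out.pixel_size == 0.5

    def test_identity_when_already_at_target(self, flat_mosaic):
        out = normalize_pixel_size(flat_mosaic, 0.5)
        assert out is flat_mosaic

    def test_physical_extent_preserved(self):
        m = _mosaic(np.zeros((900, 600, 1)), pixel_size=0.3)
        out = normalize_pixel_size(m, 0.5)
        for before, after in zip(m.extent_um, out.extent_um):
            assert abs(before - after) <= 0.5

    def test_upscaling_rejected(self):
        m = _mosaic(np.zeros((100, 100, 1)), pixel_size=1.0)
        with pytest.raises(ValueError, match="[Uu]p-scaling"):
            normalize_pixel_size(m, 0.5)

    def test_local_mean_downscale_averages(self):
        # 2x2 blocks average exactly under area-averaging
        px = np.arange(16, dtype=np.float32).reshape(4, 4, 1) / 16
        m = _mosaic(px, pixel_size=0.25)
        out = normalize_pixel_size(m, 0.5)
        expected = px[:, :, 0].reshape(2, 2, 2, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(out.pixels[:, :, 0], expected, rtol=1e-6)


class TestSplitMosaic:
    def test_four_quadrants_above_threshold(self):
        m = _mosaic(np.random.default_rng(1).random((30, 30, 2)))
        parts = split_mosaic(m, threshold=25)
        assert len(parts) == 4
        assert all(p.pixels.shape == (15, 15, 2) for p in parts)

    def test_small_mosaic_unchanged(self):
        m = _mosaic(np.zeros((20, 20, 2)))
        parts = split_mosaic(m, threshold=25)
        assert len(parts) == 1 and parts[0] is m

    def test_partition_conserves_pixel_multiset(self):
        m = _mosaic(np.random.default_rng(2).random((31, 29, 2)))
        parts = split_mosaic(m, threshold=25)
        joined = np.sort(np.concatenate([p.pixels.ravel() for p in parts]))
        np.testing.assert_array_equal(joined, np.sort(m.pixels.ravel()))

    def test_single_long_dimension_splits_in_two(self):
        m = _mosaic(np.zeros((60, 20, 1)))
        parts = split_mosaic(m, threshold=25)
        assert len(parts) == 2
        assert parts[0].pixels.shape == (30, 20, 1)


class TestFullChain:
    def test_deterministic_and_finite(self, mixed_mosaic):
        cfg = PreprocessConfig(apply_gamma=False)
        a = preprocess_mosaic(mixed_mosaic.image, cfg)
        b = preprocess_mosaic(mixed_mosaic.image, cfg)
        assert len(a) == len(b) == 1
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        assert np.isfinite(a[0].pixels).all()
        assert a[0].pixels.min() >= 0.0

    def test_glass_background_removed_cells_retained(self, artifact_mosaic):
        img = artifact_mosaic.image
        cells = artifact_mosaic.cell_union_mask()
        # dirt objects are foreground: background subtraction rightly keeps
        # them, so they are excluded from the background estimate
        bg = ~(cells | artifact_mosaic.dirt_mask)
        thg_before = img.channel("THG")
        out = subtract_background(img, radius_um=25.0)
        thg_after = out.channel("THG")
        assert thg_after[bg].mean() < 0.10 * thg_before[bg].mean()
        assert thg_after[cells].mean() >= 0.50 * thg_before[cells].mean()
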