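import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fingervein as fv
from fingervein.errors import ContractError, DetectionError


def brute_force_region(image, bounds, median_window=5):
    """Independent per-column argmax oracle for finger-boundary detection."""
    img = np.asarray(image, dtype=float)
    height = img.shape[0]
    upper, lower = [], []
    for col in range(bounds.x_left, bounds.x_right):
        ru = [fv.boundary_mask_response(img, col, y, "upper") for y in range(height)]
        rl = [fv.boundary_mask_response(img, col, y, "lower") for y in range(height)]
        upper.append(2 + int(np.argmax(ru[2 : height // 2])))
        lower.append(height // 2 + int(np.argmax(rl[height // 2 : height - 2])))

    def medfilt(seq):
        half = median_window // 2
        padded = [seq[0]] * half + list(seq) + [seq[-1]] * half
        return [
            int(statistics.median(padded[i : i + median_window])) for i in range(len(seq))
        ]

    return medfilt(upper), medfilt(lower)


class TestBoundaryMaskResponse:
    def test_band_edge_response_value_and_argmax(self, band_image):
        # dark (10) above row 100, bright (200) below: response 20*2*(200-10)
        resp = fv.boundary_mask_response(band_image, 320, 100, "upper")
        assert resp == pytest.approx(20 * 2 * (200 - 10))
        sweep = [fv.boundary_mask_response(band_image, 320, y, "upper") for y in range(480)]
        assert int(np.argmax(sweep)) == 100

    def test_lower_mask_peaks_at_bright_to_dark_transition(self, band_image):
        sweep = [fv.boundary_mask_response(band_image, 100, y, "lower") for y in range(480)]
        assert int(np.argmax(sweep)) == 400

    def test_constant_image_gives_zero(self):
        img = np.full((40, 60), 123, dtype=np.uint8)
        assert fv.boundary_mask_response(img, 30, 17, "upper") == 0.0
        assert fv.boundary_mask_response(img, 30, 17, "lower") == 0.0

    def test_out_of_range_arguments_rejected(self, band_image):
        with pytest.raises(ContractError):
            fv.boundary_mask_response(band_image, 640, 10, "upper")
        with pytest.raises(ContractError):
            fv.boundary_mask_response(band_image, 0, 10, "sideways")


class TestDetectFingerRegion:
    def test_band_boundaries_recovered(self, band_image):
        region = fv.detect_finger_region(band_image, fv.CropBounds(180, 480))
        assert np.all(np.abs(region.upper - 100) <= 1)
        assert np.all(np.abs(region.lower - 400) <= 1)

    def test_agrees_with_per_column_argmax_oracle(self, rng):
        base = rng.integers(0, 60, size=(48, 40)).astype(float)
        img = base.copy()
        img[12:36, :] += 150  # finger band with noisy texture
        bounds = fv.CropBounds(5, 35)
        region = fv.detect_finger_region(img, bounds)
        up_o, low_o = brute_force_region(img, bounds)
        np.testing.assert_array_equal(region.upper, up_o)
        np.testing.assert_array_equal(region.lower, low_o)

    def test_invalid_bounds_rejected(self, band_image):
        with pytest.raises(ContractError):
            fv.detect_finger_region(band_image, fv.CropBounds(480, 180))

    def test_detection_failure_raises_with_overlapping_search_ranges(self):
        # with overlapping custom search ranges on an inverted image, the
        # detected curves cross and the image must be rejected
        img = np.full((40, 60), 200, dtype=np.uint8)
        img[15:25, :] = 10  # dark gap: the dark-to-bright edge lies below the bright-to-dark one
        with pytest.raises(DetectionError):
            fv.detect_finger_region(
                img, fv.CropBounds(10, 50), upper_search=(2, 38), lower_search=(2, 38)
            )

    def test_custom_search_ranges_validated(self, band_image):
        with pytest.raises(ContractError):
            fv.detect_finger_region(band_image, fv.CropBounds(180, 480), upper_search=(30, 10))


class TestStretchToRectangle:
    def _flat_region(self, bounds, upper, lower):
        width = bounds.width
        return fv.FingerRegion(
            bounds, np.full(width, upper, dtype=int), np.full(width, lower, dtype=int)
        )

    def test_constant_region_maps_to_constant(self):
        img = np.full((200, 400), 90.0)
        region = self._flat_region(fv.CropBounds(50, 350), 40, 160)
        out = fv.stretch_to_rectangle(img, region)
        assert out.shape == (60, 150)
        np.testing.assert_allclose(out, 90.0)

    def test_identity_mapping_is_bit_exact(self, rng):
        img = rng.integers(0, 256, size=(100, 300)).astype(float)
        region = self._flat_region(fv.CropBounds(20, 170), 30, 90)
        out = fv.stretch_to_rectangle(img, region)
        np.testing.assert_array_equal(out, img[30:90, 20:170])

    def test_vertical_gradient_gives_linear_ramp_columns(self):
        img = np.tile(np.arange(240.0)[:, None], (1, 320))
        region = self._flat_region(fv.CropBounds(40, 280), 60, 180)
        out = fv.stretch_to_rectangle(img, region)
        expected = 60.0 + np.arange(60) * (180.0 - 60.0) / 60.0
        for j in (0, 75, 149):
            np.testing.assert_allclose(out[:, j], expected, atol=1e-9)

    def test_intensity_scaling_commutes(self, rng):
        img = rng.uniform(0, 80, size=(120, 200))
        region = self._flat_region(fv.CropBounds(10, 190), 20, 100)
        out1 = fv.stretch_to_rectangle(img * 3.0, region)
        out2 = fv.stretch_to_rectangle(img, region) * 3.0
        np.testing.assert_allclose(out1, out2, atol=1e-9)


class TestSubsample3x3:
    def test_constant_preserved(self):
        out = fv.subsample_3x3(np.full((60, 150), 42.0))
        assert out.shape == (20, 50)
        np.testing.assert_allclose(out, 42.0)

    def test_first_block_mean(self):
        img = np.zeros((60, 150))
        img[:3, :3] = np.arange(9.0).reshape(3, 3)
        assert fv.subsample_3x3(img)[0, 0] == pytest.approx(4.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ContractError):
            fv.subsample_3x3(np.zeros((50, 20)))

    @given(st.integers(0, 2**32 - 1))
    def test_total_mean_preserved(self, seed):
        img = np.random.default_rng(seed).uniform(0, 255, size=(60, 150))
        assert fv.subsample_3x3(img).mean() == pytest.approx(img.mean(), abs=1e-9)


class TestFullPreprocessing:
    def test_translation_by_multiple_of_3_keeps_same_finger_close(self):
        """Shifted copies of one finger stay closer (in code space) than different fingers."""
        cfg, bounds = fv.preset_config("good", n_people=2, n_trials=1, seed=5)
        pc = fv.PipelineConfig(bounds=bounds)
        items = list(fv.iter_database(cfg))
        img_a = items[0][1]
        img_b = items[3][1]  # different person
        shifted = np.roll(img_a, 6, axis=1)  # 6 px horizontal translation
        code_a = fv.code_image(img_a, pc)
        code_shift = fv.code_image(shifted, pc)
        code_b = fv.code_image(img_b, pc)
        assert fv.hamming(code_a, code_shift).hd < fv.hamming(code_a, code_b).hd
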