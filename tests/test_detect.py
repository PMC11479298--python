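"""Detection pipeline: grayscale, bicubic resampling, thresholding, sizing."""

import math

import numpy as np
import pytest

import papersensor as ps
from papersensor.classify import PMClass


def _keys_weight(x, a):
    ax = abs(x)
    if ax <= 1:
        return (a + 2) * ax**3 - (a + 3) * ax**2 + 1
    if ax < 2:
        return a * ax**3 - 5 * a * ax**2 + 8 * a * ax - 4 * a
    return 0.0


def bicubic_oracle(img, factor, a):
    """Brute-force 16-neighbour bicubic resampling: explicit loops over the
    4x4 stencil with edge-clamped borders.  Independent of the implementation."""
    h, w = img.shape
    oh, ow = round(factor * h), round(factor * w)
    out = np.zeros((oh, ow))
    for oy in range(oh):
        sy = (oy + 0.5) / factor - 0.5
        by = math.floor(sy)
        for ox in range(ow):
            sx = (ox + 0.5) / factor - 0.5
            bx = math.floor(sx)
            acc = 0.0
            for ky in range(-1, 3):
                wy = _keys_weight(sy - (by + ky), a)
                iy = min(max(by + ky, 0), h - 1)
                for kx in range(-1, 3):
                    wx = _keys_weight(sx - (bx + kx), a)
                    ix = min(max(bx + kx, 0), w - 1)
                    acc += wy * wx * img[iy, ix]
            out[oy, ox] = acc
    return out


class TestToGrayscale:
    @pytest.mark.parametrize(
        ("pixel", "expected"),
        [((100, 100, 100), 100), ((255, 0, 0), 76), ((255, 255, 255), 255), ((0, 255, 0), 150)],
    )
    def test_rec601_weights(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert ps.to_grayscale(img)[0, 0] == expected

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            ps.to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestBicubicUpscale:
    def test_constant_maps_to_constant(self):
        img = np.full((10, 12), 200.0)
        out = ps.bicubic_upscale(img, 2.5)
        assert out.shape == (25, 30)
        np.testing.assert_allclose(out, 200.0, rtol=1e-12)

    def test_factor_one_is_identity(self, rng):
        img = rng.random((9, 9))
        np.testing.assert_allclose(ps.bicubic_upscale(img, 1.0), img, rtol=1e-12)

    @pytest.mark.parametrize("factor", [1.5, 2.0, 2.5])
    @pytest.mark.parametrize("a", [-0.5, -0.75])
    def test_matches_bruteforce_oracle(self, rng, factor, a):
        img = rng.random((8, 8)) * 255
        out = ps.bicubic_upscale(img, factor, a=a)
        np.testing.assert_allclose(out, bicubic_oracle(img, factor, a), rtol=1e-6, atol=1e-8)

    def test_ramp_matches_oracle(self):
        img = np.add.outer(np.arange(8.0), np.arange(8.0))
        np.testing.assert_allclose(
            ps.bicubic_upscale(img, 2.0), bicubic_oracle(img, 2.0, -0.5), rtol=1e-6, atol=1e-8
        )

    def test_rejects_non_positive_factor(self):
        with pytest.raises(ValueError):
            ps.bicubic_upscale(np.zeros((4, 4)), 0.0)


class TestAdaptiveThreshold:
    def test_constant_image_has_no_foreground(self):
        img = np.full((30, 30), 180, dtype=np.uint8)
        assert not ps.adaptive_threshold(img, 15, 10.0).any()

    def test_all_dark_image_has_no_foreground(self):
        img = np.zeros((30, 30), dtype=np.uint8)
        assert not ps.adaptive_threshold(img, 15, 10.0).any()

    def test_single_dark_pixel_matches_windowed_mean_oracle(self):
        """Foreground equals a direct per-pixel reflected-window mean check."""
        img = np.full((21, 21), 255, dtype=np.uint8)
        img[10, 10] = 0
        block, offset = 15, 10.0
        mask = ps.adaptive_threshold(img, block, offset)

        pad = block // 2
        padded = np.pad(img.astype(float), pad, mode="reflect")
        for y in range(21):
            for x in range(21):
                local = padded[y : y + block, x : x + block].mean()
                assert mask[y, x] == (img[y, x] < local - offset)
        assert mask[10, 10]
        assert mask.sum() == 1

    def test_rejects_even_block(self):
        with pytest.raises(ValueError):
            ps.adaptive_threshold(np.zeros((8, 8), dtype=np.uint8), 14, 5.0)


class TestExtractParticles:
    def test_empty_mask_gives_empty_list(self):
        assert ps.extract_particles(np.zeros((10, 10), bool), 0.5, 1.0) == []

    def test_equivalent_diameter_closed_form(self):
        """A 78-px component at 1 px/µm sizes to 2·sqrt(78/pi) ≈ 9.97 µm (PM10)."""
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:78] = True  # a 78-px blob: the formula is shape-free
        mask = mask.reshape(20, 20)
        (particle,) = ps.extract_particles(mask, 0.5, 1.0)
        assert particle.area_px == 78
        assert particle.equiv_diameter_um == pytest.approx(2 * math.sqrt(78 / math.pi))
        assert particle.pm_class is PMClass.PM10

    def test_corner_touching_blobs_merge_under_8_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches at one corner
        assert len(ps.extract_particles(mask, 0.5, 1.0)) == 1

    def test_min_area_filters_specks(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = True
        mask[5:8, 5:8] = True
        parts = ps.extract_particles(mask, 2.0, 1.0)
        assert len(parts) == 1
        assert parts[0].area_px == 9

    def test_resolution_scales_diameter(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True  # area 100 px
        (at1,) = ps.extract_particles(mask, 0.5, 1.0)
        (at2,) = ps.extract_particles(mask, 0.5, 2.0)
        assert at2.equiv_diameter_um == pytest.approx(at1.equiv_diameter_um / 2.0)


class TestCalibration:
    def test_from_frame(self):
        cal = ps.CalibrationInfo.from_frame(6.0, 60000)
        assert cal.px_per_cm == pytest.approx(1e4)
        assert cal.resolution_px_per_um == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            ps.CalibrationInfo(px_per_cm=bad)


class TestDetectPipeline:
    def test_exact_count_on_clean_pm10_image(self, calibration):
        """100 well-separated PM10 particles on a clean synthetic image are
        all recovered at the default parameters."""
        spec = ps.SensorImageSpec(width_px=1500, height_px=1500)
        parts = ps.sample_particles(spec, 100, (0, 0, 1), min_gap_px=4.0, seed=2)
        img, gt = ps.render_sensor_image(spec, parts, seed=2)
        result = ps.detect(img, ps.DetectionParams(), calibration)
        assert result.n_total == gt.n_total == 100
        assert result.n_pm10 == 100

    def test_blank_image_detects_nothing(self, calibration):
        spec = ps.SensorImageSpec(width_px=500, height_px=500)
        img, _ = ps.render_sensor_image(spec, [], seed=0)
        result = ps.detect(img, ps.DetectionParams(), calibration)
        assert result.n_total == 0
        assert result.dots_per_cm2 == 0.0

    def test_deterministic(self, small_spec, calibration):
        parts = ps.sample_particles(small_spec, 20, (0, 0, 1), seed=8)
        img, _ = ps.render_sensor_image(small_spec, parts, seed=8)
        r1 = ps.detect(img, ps.DetectionParams(), calibration)
        r2 = ps.detect(img, ps.DetectionParams(), calibration)
        assert r1 == r2

    @pytest.mark.parametrize("diameter", [3.0, 4.0, 6.0, 8.0, 10.0])
    def test_sizing_within_one_micron(self, calibration, diameter):
        """Isolated disks ≥ 3 µm size to within ±1 µm of ground truth."""
        spec = ps.SensorImageSpec(width_px=200, height_px=200)
        p = ps.ParticleGT(0, 100.3, 99.6, diameter, 60, ps.pm_class(diameter))
        img, _ = ps.render_sensor_image(spec, [p], seed=4)
        result = ps.detect(img, ps.DetectionParams(), calibration)
        assert result.n_total == 1
        assert result.particles[0].equiv_diameter_um == pytest.approx(diameter, abs=1.0)

    def test_upscaling_path_recovers_counts_at_half_resolution(self):
        """An image captured at 0.5 px/µm is bicubically upscaled to the
        1 px/µm working resolution and still counts correctly."""
        spec = ps.SensorImageSpec(width_px=400, height_px=400, resolution_px_per_um=0.5)
        parts = ps.sample_particles(spec, 20, (0, 0, 1), min_gap_px=8.0, seed=6)
        parts = [p for p in parts if p.diameter_um >= 5.0]
        img, _ = ps.render_sensor_image(spec, parts, seed=6)
        cal = ps.CalibrationInfo(px_per_cm=5000)  # 0.5 px/µm native
        result = ps.detect(img, ps.DetectionParams(), cal)
        assert result.n_total == len(parts)
        for det in result.particles:
            assert det.pm_class is not PMClass.OVERSIZE

    def test_dots_per_cm2_and_level(self, calibration):
        spec = ps.SensorImageSpec(width_px=2000, height_px=2000)  # 0.04 cm²
        parts = ps.sample_particles(spec, 50, (0, 0, 1), min_gap_px=4.0, seed=1)
        img, _ = ps.render_sensor_image(spec, parts, seed=1)
        result = ps.detect(img, ps.DetectionParams(), calibration)
        assert result.dots_per_cm2 == pytest.approx(result.n_total / 0.04)
        assert result.pollution_level is ps.DustLevel.VERY_HIGH

    def test_missing_calibration_raises(self, small_spec):
        img, _ = ps.render_sensor_image(small_spec, [], seed=0)
        with pytest.raises(ValueError):
            ps.detect(img, ps.DetectionParams())

    def test_result_serializes(self, small_spec, calibration, tmp_path):
        parts = ps.sample_particles(small_spec, 5, (0, 0, 1), seed=3)
        img, _ = ps.render_sensor_image(small_spec, parts, seed=3)
        result = ps.detect(img, ps.DetectionParams(), calibration)
        result.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert len(result.to_dataframe()) == result.n_total
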