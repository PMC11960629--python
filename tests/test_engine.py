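"""OCT forward model and reconstruction chain: physics and mapping checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octsex.engine import (
    BScan,
    Interferogram,
    ScanConfig,
    SourceSpectrum,
    axial_resolution_um,
    log_compress_to_u8,
    normalize_bscan,
    reconstruct_aline,
    reference_background,
    scan_bscan,
    simulate_interferogram,
)
from octsex.phantom import ReflectivityMap


def _fwhm_um(envelope: np.ndarray, pitch_um: float) -> float:
    peak = int(np.argmax(envelope))
    fine = np.linspace(max(peak - 12, 0), min(peak + 12, len(envelope) - 1), 4001)
    interp = np.interp(fine, np.arange(len(envelope)), envelope)
    above = fine[interp >= interp.max() / 2]
    return (above.max() - above.min()) * pitch_um


class TestSourceSpectrum:
    def test_defaults_match_system(self, source):
        assert source.center_wavelength_nm == 840.0
        assert source.n_spectral_samples == 2048

    def test_bandwidth_yields_10um_coherence_length(self, source):
        assert axial_resolution_um(source) == pytest.approx(10.0, rel=0.02)

    @pytest.mark.parametrize("n", [0, 3, 1000])
    def test_rejects_non_power_of_two_sampling(self, n):
        with pytest.raises(ValueError):
            SourceSpectrum(n_spectral_samples=n)


class TestInterferogram:
    def test_zero_profile_gives_reference_spectrum_only(self, source):
        ig = simulate_interferogram(np.zeros(500), source)
        np.testing.assert_allclose(
            ig.intensities, reference_background(source), rtol=1e-12
        )
        env = reconstruct_aline(ig, 500, source=source, background=reference_background(source))
        assert env.max() == pytest.approx(0.0, abs=1e-9)

    def test_intensities_nonnegative(self, source):
        rng = np.random.default_rng(0)
        ig = simulate_interferogram(rng.random(300), source)
        assert ig.intensities.min() >= 0

    def test_single_reflector_fringe_frequency(self, source):
        # oracle: brute-force discrete Fourier sum locates the fringe at 2z,
        # i.e. at the depth bin z/depth_pitch
        depth_px, pitch = 400, 4.0
        prof = np.zeros(depth_px)
        prof[123] = 0.8
        ig = simulate_interferogram(prof, source, depth_pitch_um=pitch)
        sig = ig.intensities - reference_background(source, pitch)
        n = len(sig)
        bins = np.arange(depth_px)
        dft = np.abs(np.exp(-2j * np.pi * np.outer(bins, np.arange(n)) / n) @ sig)
        assert int(np.argmax(dft)) == 123

    def test_empty_profile_rejected(self, source):
        with pytest.raises(ValueError, match="empty"):
            simulate_interferogram(np.array([]), source)

    def test_out_of_range_profile_rejected(self, source):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_interferogram(np.array([0.5, 1.5]), source)


class TestReconstruct:
    def test_pure_cosine_fringe_peaks_at_matching_bin(self):
        # synthetic fringe: frequency m cycles across the record -> bin m
        n, m = 512, 37
        sig = 1.0 + np.cos(2 * np.pi * m * np.arange(n) / n)
        env = reconstruct_aline(Interferogram(sig, 4.0), 200)
        assert int(np.argmax(env)) == m

    def test_constant_spectrum_is_dc_only(self):
        env = reconstruct_aline(Interferogram(np.full(256, 3.0), 4.0), 100)
        assert env[1:].max() == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_rejected(self, source):
        with pytest.raises(ValueError, match="does not match"):
            reconstruct_aline(Interferogram(np.ones(512), 4.0), 100, source=source)

    def test_axial_psf_fwhm_close_to_10um(self, source):
        prof = np.zeros(600)
        prof[300] = 0.5
        ig = simulate_interferogram(prof, source)
        env = reconstruct_aline(ig, 600, source=source,
                                background=reference_background(source))
        fwhm = _fwhm_um(env, 4.0)
        assert fwhm == pytest.approx(10.0, rel=0.20)


class TestNormalize:
    def test_uniform_grid_becomes_ones(self):
        out = normalize_bscan(np.full((5, 7), 0.3))
        np.testing.assert_array_equal(out, np.ones((5, 7)))

    def test_matches_direct_division(self):
        rng = np.random.default_rng(1)
        grid = rng.random((20, 30)) * 7.0
        np.testing.assert_allclose(normalize_bscan(grid), grid / grid.max(), rtol=1e-15)

    def test_max_is_exactly_one_and_idempotent(self):
        rng = np.random.default_rng(2)
        grid = rng.random((10, 10))
        out = normalize_bscan(grid)
        assert out.max() == 1.0
        np.testing.assert_array_equal(normalize_bscan(out), out)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_bscan(np.zeros((4, 4)))


class TestLogCompress:
    def test_endpoints(self):
        out = log_compress_to_u8(np.array([1.0, 10 ** (-50 / 20), 0.0]))
        assert out[0] == 255
        assert out[1] == 0
        assert out[2] == 0

    def test_midpoint_of_db_ramp(self):
        # -25 dB with a -50 dB floor sits halfway up the ramp
        out = log_compress_to_u8(np.array([10 ** (-25 / 20)]), floor_db=-50.0)
        assert abs(int(out[0]) - 128) <= 1

    def test_nonnegative_floor_rejected(self):
        with pytest.raises(ValueError, match="floor_db"):
            log_compress_to_u8(np.array([0.5]), floor_db=0.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_amplitude(self, values):
        x = np.sort(np.asarray(values))
        out = log_compress_to_u8(x)
        assert np.all(np.diff(out.astype(int)) >= 0)


class TestScanBScan:
    def test_default_output_is_1000x600(self, source):
        rng = np.random.default_rng(0)
        cfg = ScanConfig()
        rmap = ReflectivityMap(rng.random((1000, 1000)) * 0.5, 4.0, 4.0)
        bscan = scan_bscan(rmap, source, cfg)
        assert bscan.pixels.shape == (600, 1000)
        assert bscan.pixels.dtype == np.uint8

    def test_single_reflector_lands_at_expected_pixel(self, small_source, small_scan):
        values = np.zeros((small_scan.depth_pixels, small_scan.n_alines))
        row, col = 70, 33
        values[row, col] = 0.9
        rmap = ReflectivityMap(values, small_scan.depth_pitch_um, small_scan.lateral_pitch_um)
        bscan = scan_bscan(rmap, small_source, small_scan)
        r, c = np.unravel_index(np.argmax(bscan.pixels), bscan.pixels.shape)
        assert abs(r - row) <= 1
        assert c == col

    def test_localization_across_depths(self, small_source, small_scan):
        # reflectors along a diagonal recover within ±1 depth pixel each
        n = 10
        values = np.zeros((small_scan.depth_pixels, small_scan.n_alines))
        rows = np.linspace(10, small_scan.depth_crop - 10, n).astype(int)
        cols = np.linspace(5, small_scan.n_alines - 5, n).astype(int)
        values[rows, cols] = 0.9
        rmap = ReflectivityMap(values, small_scan.depth_pitch_um, small_scan.lateral_pitch_um)
        bscan = scan_bscan(rmap, small_source, small_scan)
        for r, c in zip(rows, cols):
            assert abs(int(np.argmax(bscan.pixels[:, c])) - r) <= 1

    def test_empty_map_noise_off_propagates_rejection(self, small_source, small_scan):
        rmap = ReflectivityMap(
            np.zeros((small_scan.depth_pixels, small_scan.n_alines)),
            small_scan.depth_pitch_um, small_scan.lateral_pitch_um,
        )
        with pytest.raises(ValueError, match="all-zero"):
            scan_bscan(rmap, small_source, small_scan)

    def test_empty_map_with_noise_has_no_structure(self, small_source, small_scan):
        # a noise-only frame normalizes to its own noise maximum, so it is a
        # featureless grey field: no saturated pixels beyond the scale factor
        # itself and no bright connected structure
        rmap = ReflectivityMap(
            np.zeros((small_scan.depth_pixels, small_scan.n_alines)),
            small_scan.depth_pitch_um, small_scan.lateral_pitch_um,
        )
        bscan = scan_bscan(rmap, small_source, small_scan, noise_floor=0.01, rng=0)
        assert (bscan.pixels >= 250).mean() < 1e-3
        assert bscan.pixels.std() < 40

    def test_geometry_mismatch_rejected(self, small_source, small_scan):
        rmap = ReflectivityMap(np.zeros((10, 10)), 4.0, 4.0)
        with pytest.raises(ValueError, match="does not match"):
            scan_bscan(rmap, small_source, small_scan)

    def test_deterministic_under_seed(self, small_source, small_scan):
        rng = np.random.default_rng(5)
        values = rng.random((small_scan.depth_pixels, small_scan.n_alines)) * 0.4
        rmap = ReflectivityMap(values, small_scan.depth_pitch_um, small_scan.lateral_pitch_um)
        a = scan_bscan(rmap, small_source, small_scan, speckle_scale=0.2, noise_floor=0.02, rng=7)
        b = scan_bscan(rmap, small_source, small_scan, speckle_scale=0.2, noise_floor=0.02, rng=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestScanConfig:
    def test_lateral_pitch_is_4um_at_defaults(self):
        assert ScanConfig().lateral_pitch_um == 4.0

    def test_crop_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            ScanConfig(depth_crop=1200)


def test_bscan_requires_uint8():
    with pytest.raises(ValueError, match="uint8"):
        BScan(pixels=np.zeros((4, 4), dtype=np.float64))
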