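import numpy as np
import pytest

from afmtopo import (HeightMap, ORDER_I, ORDER_II, SpectralWindow,
                     bandpass_surface, cell_patch_spectrum, detrend,
                     make_roughness_field, make_scene, period_from_frequency,
                     profile_spectrum, scene_from_preset, spectral_summary)

from conftest import centered_cosine


class TestDetrend:
    def test_pure_ramp_detrends_to_zero(self):
        ramp = 3.0 + 0.5 * np.arange(100)
        np.testing.assert_allclose(detrend(ramp), 0.0, atol=1e-9)

    def test_cosine_plus_ramp_recovers_cosine(self):
        cos = centered_cosine(256, 10.0, 320.0, 7.0)
        out = detrend(cos + 5.0 + 0.01 * np.arange(256))
        np.testing.assert_allclose(out, cos, atol=1e-9 * np.abs(cos).max())

    def test_idempotent(self, rng):
        x = rng.normal(0, 3, 200)
        once = detrend(x)
        np.testing.assert_allclose(detrend(once), once, atol=1e-10)

    def test_plane_removed_from_2d(self, rng):
        y, x = np.mgrid[0:40, 0:50]
        field = 2.0 + 0.3 * x - 0.7 * y
        np.testing.assert_allclose(detrend(field), 0.0, atol=1e-9)


class TestProfileSpectrum:
    def test_on_grid_cosine_gives_amplitude_squared(self):
        n, dx, A, period = 512, 5000.0 / 512, 40.0, 1000.0
        spec = profile_spectrum((centered_cosine(n, dx, period, A), dx))
        i = np.argmax(spec.intensities)
        assert spec.frequencies[i] == pytest.approx(1e-3, rel=1e-12)
        assert spec.intensities[i] == pytest.approx(A ** 2, rel=1e-6)
        others = np.delete(spec.intensities, i)
        assert others.max() < 1e-9 * A ** 2

    def test_two_cosines_each_recovered(self):
        n, dx = 512, 9.765625
        h = centered_cosine(n, dx, 1000.0, 40.0) \
            + centered_cosine(n, dx, 250.0, 3.0)
        spec = profile_spectrum((h, dx))
        s_at = dict(zip(np.round(spec.frequencies, 9), spec.intensities))
        assert s_at[np.round(1 / 1000, 9)] == pytest.approx(1600.0, rel=1e-6)
        assert s_at[np.round(1 / 250, 9)] == pytest.approx(9.0, rel=1e-6)

    def test_zero_profile_gives_zero_spectrum(self):
        spec = profile_spectrum((np.zeros(64), 10.0))
        assert np.all(spec.intensities == 0.0)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_spectrum((np.arange(5, dtype=float), 1.0))

    def test_parseval_odd_length(self, rng):
        h = rng.normal(0, 5, 511)
        spec = profile_spectrum((h, 10.0))
        var = detrend(h).var()
        assert spec.power() == pytest.approx(var, rel=1e-9)

    def test_parseval_even_length_with_nyquist_account(self, rng):
        h = rng.normal(0, 5, 512)
        d = detrend(h)
        nyq_power = np.abs(np.fft.rfft(d)[-1]) ** 2 / 512 ** 2
        spec = profile_spectrum((h, 10.0))
        assert spec.power() + nyq_power == pytest.approx(d.var(), rel=1e-9)

    def test_shift_and_ramp_invariance(self, rng):
        h = rng.normal(0, 5, 256)
        base = profile_spectrum((h, 10.0))
        moved = profile_spectrum((h + 17.0 + 0.3 * np.arange(256), 10.0))
        np.testing.assert_allclose(moved.intensities, base.intensities,
                                   rtol=1e-7, atol=1e-9)

    def test_scale_equivariance(self, rng):
        h = rng.normal(0, 5, 256)
        s1 = profile_spectrum((h, 10.0))
        s2 = profile_spectrum((3.0 * h, 10.0))
        np.testing.assert_allclose(s2.intensities, 9.0 * s1.intensities,
                                   rtol=1e-9)


class TestSpectralSummary:
    @pytest.mark.parametrize("nu,L", [(0.001, 1000.0), (0.002, 500.0),
                                      (0.008, 125.0), (0.5, 2.0)])
    def test_period_from_frequency(self, nu, L):
        assert period_from_frequency(nu) == pytest.approx(L)

    def test_non_positive_frequency_rejected(self):
        with pytest.raises(ValueError):
            period_from_frequency(0.0)

    def test_summary_finds_in_window_peak(self):
        n, dx = 512, 9.765625
        h = centered_cosine(n, dx, 1000.0, 40.0) \
            + centered_cosine(n, dx, 125.0, 10.0)
        spec = profile_spectrum((h, dx))
        s1 = spectral_summary(spec, ORDER_I)
        s2 = spectral_summary(spec, ORDER_II)
        assert s1.L_max_nm == pytest.approx(1000.0)
        assert s1.S_max_nm2 == pytest.approx(1600.0, rel=1e-6)
        assert s2.L_max_nm == pytest.approx(125.0)
        assert s2.S_max_nm2 == pytest.approx(100.0, rel=1e-6)

    def test_flat_spectrum_ties_break_to_lowest_frequency(self):
        spec = profile_spectrum((np.zeros(64), 10.0))
        summ = spectral_summary(spec, SpectralWindow("w", 50.0, 300.0))
        assert summ.S_max_nm2 == 0.0
        in_window = spec.frequencies[(spec.frequencies >= 1 / 300.0)
                                     & (spec.frequencies <= 1 / 50.0)]
        assert summ.nu_max_per_nm == in_window[0]

    def test_window_outside_spectrum_range_rejected(self):
        spec = profile_spectrum((np.zeros(64), 10.0))
        with pytest.raises(ValueError):
            spectral_summary(spec, SpectralWindow("w", 1.0, 5.0))


class TestBandpassSurface:
    @staticmethod
    def _cosine_map(period, n=256, field=5000.0):
        dx = field / n
        x = (np.arange(n) + 0.5) * dx
        return HeightMap(np.tile(40.0 * np.cos(2 * np.pi * x / period), (n, 1)),
                         dx)

    def test_in_band_identity(self):
        hm = self._cosine_map(5000.0 / 6)    # ~833 nm, inside order I
        out = bandpass_surface(hm, ORDER_I)
        ref = detrend(hm).heights
        np.testing.assert_allclose(out.heights, ref,
                                   atol=1e-6 * np.abs(ref).max())

    def test_out_of_band_rejection(self):
        hm = self._cosine_map(5000.0 / 6)
        out = bandpass_surface(hm, ORDER_II)
        assert np.abs(out.heights).max() < 1e-9 * 40.0

    def test_variance_partition_on_white_noise(self, rng):
        hm = HeightMap(rng.normal(0, 3, (128, 128)), 9.77)
        total = detrend(hm).heights.var()
        v1 = bandpass_surface(hm, ORDER_I).heights.var()
        v2 = bandpass_surface(hm, ORDER_II).heights.var()
        assert v1 + v2 <= total * (1 + 1e-9)

    def test_output_zero_mean(self, rng):
        hm = HeightMap(rng.normal(5, 3, (64, 64)), 9.77)
        out = bandpass_surface(hm, ORDER_II)
        assert abs(out.heights.mean()) < 1e-9

    def test_window_above_nyquist_rejected(self):
        hm = HeightMap(np.zeros((64, 64)), 200.0)   # Nyquist at 400 nm period
        with pytest.raises(ValueError):
            bandpass_surface(hm, ORDER_II)


class TestPatchSpectrum:
    def test_roughness_patch_recovery_over_seeds(self):
        """Generator round trip: band-1 period 1000 nm, amplitude 40 nm."""
        s_errors, L_ok = [], 0
        for seed in range(20):
            hm, truth = make_scene(scene_from_preset("membrane_patch",
                                                     seed=seed))
            _, summaries = cell_patch_spectrum(hm, None, 5000.0)
            summ = summaries["order_I"]
            s_errors.append(abs(summ.S_max_nm2 - 1600.0) / 1600.0)
            dnu = 1.0 / 5000.0
            L_ok += abs(summ.nu_max_per_nm - 1e-3) <= dnu + 1e-12
        assert np.median(s_errors) <= 0.15
        assert L_ok == 20

    def test_second_order_recovery(self):
        vals = []
        for seed in range(10):
            hm, _ = make_scene(scene_from_preset("membrane_patch", seed=seed))
            _, summaries = cell_patch_spectrum(hm, None, 5000.0)
            vals.append(summaries["order_II"].S_max_nm2)
        assert np.median(np.abs(np.array(vals) - 2.3 ** 2) / 2.3 ** 2) <= 0.15

    def test_noise_floor_without_roughness(self):
        hm, _ = make_scene(scene_from_preset(
            "membrane_patch", seed=4, band1_amplitude_nm=0.0,
            band2_amplitude_nm=0.0))
        _, summaries = cell_patch_spectrum(hm, None, 5000.0)
        noise_var = 1.0   # substrate noise SD is 1 nm
        assert summaries["order_II"].S_max_nm2 < 5.0 * noise_var

    def test_doubling_heights_quadruples_intensity(self):
        hm, _ = make_scene(scene_from_preset("membrane_patch", seed=5))
        doubled = HeightMap(hm.heights * 2.0, hm.pixel_size_nm)
        _, s1 = cell_patch_spectrum(hm, None, 5000.0)
        _, s2 = cell_patch_spectrum(doubled, None, 5000.0)
        for label in ("order_I", "order_II"):
            assert s2[label].S_max_nm2 == pytest.approx(
                4.0 * s1[label].S_max_nm2, rel=1e-9)
            assert s2[label].L_max_nm == s1[label].L_max_nm

    def test_cell_too_small_for_patch(self, rng):
        hm = HeightMap(rng.normal(0, 1, (64, 64)), 10.0)   # 640 nm field
        with pytest.raises(ValueError):
            cell_patch_spectrum(hm, None, 5000.0)
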