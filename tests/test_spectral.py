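"""Spectral processing: regridding, baselines, ratios, peak decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flymap as fm
from flymap.simulate import SpectralPeak, SpectrumDesign
from flymap.spectral import RamanSpectrum

GAUSS_W = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian(nu, center, amp, fwhm):
    sigma = fwhm / GAUSS_W
    return amp * np.exp(-0.5 * ((nu - center) / sigma) ** 2)


class TestRegrid:
    def test_affine_signal_is_exact(self):
        rng = np.random.default_rng(0)
        w = np.sort(rng.uniform(1000, 1100, 80))
        w[0], w[-1] = 1000.0, 1100.0
        s = RamanSpectrum(w, 3.0 * w + 7.0)
        out = fm.regrid(s)
        assert np.allclose(out.intensities, 3.0 * out.wavenumbers + 7.0, atol=1e-9)
        assert np.allclose(np.diff(out.wavenumbers), 1.0)

    def test_idempotent_on_uniform_grid(self):
        w = np.arange(900.0, 1000.0 + 1)
        s = RamanSpectrum(w, np.sin(w / 30))
        out = fm.regrid(s)
        assert np.array_equal(out.wavenumbers, w)
        assert np.allclose(out.intensities, s.intensities)

    def test_peak_position_shift_below_one_wavenumber(self):
        w = np.arange(2800.0, 2900.0 + 0.5, 0.5)
        s = RamanSpectrum(w, gaussian(w, 2850.3, 1.0, 20))
        out = fm.regrid(s, step=1.0)
        peak_pos = out.wavenumbers[np.argmax(out.intensities)]
        assert abs(peak_pos - 2850.3) < 1.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            RamanSpectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))


class TestBackgroundAndAveraging:
    def test_self_subtraction_is_zero(self):
        w = np.arange(100.0, 200.0 + 1)
        s = RamanSpectrum(w, np.cos(w))
        assert np.allclose(fm.subtract_background(s, s).intensities, 0.0)

    def test_constant_background_removed(self):
        w = np.arange(100.0, 200.0 + 1)
        signal = gaussian(w, 150, 1.0, 10)
        s = RamanSpectrum(w, signal + 5.0)
        bg = RamanSpectrum(w, np.full(w.size, 5.0))
        assert np.allclose(fm.subtract_background(s, bg).intensities, signal)

    def test_grid_mismatch_rejected(self):
        a = RamanSpectrum(np.arange(10.0), np.zeros(10))
        b = RamanSpectrum(np.arange(1.0, 11.0), np.zeros(10))
        with pytest.raises(ValueError, match="grid"):
            fm.subtract_background(a, b)

    def test_noisy_background_residual_within_standard_error(self):
        noise_sd, n = 0.05, 1001
        w = np.arange(1000.0, 2000.0 + 1)
        rng = np.random.default_rng(3)
        s = RamanSpectrum(w, rng.normal(0, noise_sd, n))
        bg = RamanSpectrum(w, np.zeros(n))
        resid = fm.subtract_background(s, bg).intensities
        assert abs(resid.mean()) < 2 * noise_sd / np.sqrt(n)

    def test_average_identity_and_cancellation(self):
        w = np.arange(50.0, 150.0 + 1)
        s = RamanSpectrum(w, np.sin(w))
        assert np.allclose(fm.average_spectra([s]).intensities, s.intensities)
        neg = RamanSpectrum(w, -s.intensities)
        assert np.allclose(fm.average_spectra([s, neg]).intensities, 0.0)

    def test_averaging_reduces_noise_as_sqrt_n(self):
        d = SpectrumDesign(peaks=[SpectralPeak(1295, 1.0, 14)], noise_sd=0.1,
                           grid=(1200, 1400, 1))
        clean, _ = fm.generate_spectrum(
            SpectrumDesign(peaks=d.peaks, noise_sd=0.0, grid=d.grid)
        )
        reps = []
        for seed in range(100):
            noisy, _ = fm.generate_spectrum(
                SpectrumDesign(peaks=d.peaks, noise_sd=0.1, grid=d.grid, seed=seed)
            )
            reps.append(noisy)
        avg = fm.average_spectra(reps)
        rms = np.sqrt(np.mean((avg.intensities - clean.intensities) ** 2))
        assert rms < 0.02  # 2x the standard error 0.1 / sqrt(100)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fm.average_spectra([])


class TestBaselineCorrection:
    def test_flat_spectrum_flattens_to_zero(self):
        w = np.arange(1000.0, 1500.0 + 1)
        out = fm.baseline_correct(RamanSpectrum(w, np.full(w.size, 5.0)))
        assert np.all(np.abs(out.intensities) < 1e-6 * 5.0)

    def test_zero_spectrum_stays_zero(self):
        w = np.arange(1000.0, 1500.0 + 1)
        out = fm.baseline_correct(RamanSpectrum(w, np.zeros(w.size)))
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_peak_on_sloped_baseline_preserved(self):
        d = SpectrumDesign(peaks=[SpectralPeak(1440, 1.0, 15)],
                           baseline_coeffs=(0.0, 0.001), grid=(1200, 1700, 1))
        s, _ = fm.generate_spectrum(d)
        out = fm.baseline_correct(s)
        amp = out.intensities[np.argmin(np.abs(out.wavenumbers - 1440))]
        assert amp == pytest.approx(1.0, rel=0.03)

    def test_invalid_parameters_rejected(self):
        w = np.arange(10.0, 100.0)
        s = RamanSpectrum(w, np.zeros(w.size))
        with pytest.raises(ValueError):
            fm.baseline_correct(s, lam=-1.0)
        with pytest.raises(ValueError):
            fm.baseline_correct(s, p=0.0)


class TestVectorNormalize:
    def test_three_four_five(self):
        s = RamanSpectrum(np.array([0.0, 1.0]), np.array([3.0, 4.0]))
        assert np.allclose(fm.vector_normalize(s).intensities, [0.6, 0.8])

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(7)
        w = np.arange(100.0, 200.0 + 1)
        s = RamanSpectrum(w, rng.normal(1.0, 0.3, w.size))
        once = fm.vector_normalize(s)
        scaled = fm.vector_normalize(RamanSpectrum(w, 10.0 * s.intensities))
        assert np.allclose(once.intensities, scaled.intensities, atol=1e-12)
        twice = fm.vector_normalize(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-12)
        assert np.linalg.norm(once.intensities) == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_rejected(self):
        s = RamanSpectrum(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError, match="all-zero"):
            fm.vector_normalize(s)


class TestBandIntensityAndRatio:
    def test_constant_spectrum(self):
        w = np.arange(2000.0, 3000.0 + 1)
        s = RamanSpectrum(w, np.full(w.size, 3.5))
        assert fm.band_intensity(s, 2850) == pytest.approx(3.5)

    def test_gaussian_window_mean_matches_analytic(self):
        """The +-2 cm^-1 windowed mean of a fwhm-20 Gaussian equals the mean
        of the analytic curve over the window's grid points (and is within
        0.006 of the continuous-integral mean 0.9908)."""
        w = np.arange(2700.0, 3000.0 + 1)
        s = RamanSpectrum(w, gaussian(w, 2850, 1.0, 20))
        got = fm.band_intensity(s, 2850, halfwidth=2)
        grid_pts = np.arange(2848.0, 2853.0)
        expected = gaussian(grid_pts, 2850, 1.0, 20).mean()
        assert got == pytest.approx(expected, abs=1e-12)
        sigma = 20 / GAUSS_W
        xs = np.linspace(-2, 2, 20001)
        continuous = np.trapezoid(np.exp(-0.5 * (xs / sigma) ** 2), xs) / 4.0
        assert got == pytest.approx(continuous, abs=0.006)

    def test_window_far_from_peaks_is_zero(self):
        w = np.arange(1800.0, 3000.0 + 1)
        s = RamanSpectrum(w, gaussian(w, 2850, 1.0, 20))
        assert fm.band_intensity(s, 2000) == pytest.approx(0.0, abs=1e-10)

    def test_window_outside_grid_rejected(self):
        w = np.arange(2000.0, 2100.0 + 1)
        s = RamanSpectrum(w, np.ones(w.size))
        with pytest.raises(ValueError, match="outside"):
            fm.band_intensity(s, 2099.5, halfwidth=2)

    def test_equal_shape_peaks_give_amplitude_ratio(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(2140, 0.5, 20), SpectralPeak(2850, 1.0, 20)],
            grid=(1800, 3100, 1),
        )
        s, _ = fm.generate_spectrum(d)
        assert fm.band_ratio(s, 2140, 2850) == pytest.approx(0.5, abs=1e-9)

    def test_scale_invariance(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(2140, 0.5, 20), SpectralPeak(2850, 1.0, 20)],
            grid=(1800, 3100, 1),
        )
        s, _ = fm.generate_spectrum(d)
        r1 = fm.band_ratio(s, 2140, 2850)
        r2 = fm.band_ratio(RamanSpectrum(s.wavenumbers, 1e3 * s.intensities), 2140, 2850)
        assert abs(r1 - r2) < 1e-12

    def test_ratio_identical_before_and_after_vector_normalize(self):
        """Ratios on unprocessed spectra equal ratios after normalization:
        numerator and denominator scale together."""
        d = SpectrumDesign(
            peaks=[SpectralPeak(2140, 0.5, 20), SpectralPeak(2850, 1.0, 20)],
            noise_sd=0.002, grid=(1800, 3100, 1), seed=9,
        )
        s, _ = fm.generate_spectrum(d)
        r_raw = fm.band_ratio(s, 2140, 2850)
        r_norm = fm.band_ratio(fm.vector_normalize(s), 2140, 2850)
        assert abs(r_raw - r_norm) < 1e-12

    def test_noisy_ratio_monte_carlo(self):
        """1% noise perturbs the 0.5 amplitude ratio by well under 0.02."""
        ratios = []
        for seed in range(50):
            d = SpectrumDesign(
                peaks=[SpectralPeak(2140, 0.5, 20), SpectralPeak(2850, 1.0, 20)],
                noise_sd=0.01, grid=(1800, 3100, 1), seed=seed,
            )
            s, _ = fm.generate_spectrum(d)
            ratios.append(fm.band_ratio(s, 2140, 2850))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.02)

    def test_nonpositive_denominator_rejected(self):
        w = np.arange(2000.0, 3000.0 + 1)
        s = RamanSpectrum(w, np.zeros(w.size))
        with pytest.raises(ValueError, match="non-positive"):
            fm.band_ratio(s, 2140, 2850)


class TestPeakFitting:
    def test_noiseless_gaussian_recovered_exactly(self):
        d = SpectrumDesign(peaks=[SpectralPeak(2885, 0.8, 18)], grid=(2800, 3050, 1))
        s, _ = fm.generate_spectrum(d)
        (peak,) = [p for p in fm.fit_peaks(s, (2800, 3050), [2885]) if p.amplitude > 1e-3]
        assert peak.center == pytest.approx(2885, rel=1e-3)
        assert peak.amplitude == pytest.approx(0.8, rel=1e-3)
        assert peak.fwhm == pytest.approx(18, rel=1e-3)

    def test_overlapping_pair_areas_within_two_percent(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(2850, 1.0, 20), SpectralPeak(2885, 0.8, 20)],
            noise_sd=0.005, grid=(2750, 3000, 1), seed=2,
        )
        s, truth = fm.generate_spectrum(d)
        fits = fm.fit_peaks(s, (2750, 3000), [2850, 2885])
        for fit, true in zip(fits, truth["peaks"]):
            assert fit.area == pytest.approx(true["area"], rel=0.02)

    def test_flat_window_fits_to_nothing(self):
        w = np.arange(2800.0, 3050.0 + 1)
        s = RamanSpectrum(w, np.zeros(w.size))
        fits = fm.fit_peaks(s, (2800, 3050), [2850, 2885])
        assert all(p.amplitude < 1e-6 for p in fits)


# CH-stretch fixture with ordered-lipid bandwidths (13-18 cm^-1): the
# pronounced 2885 band and narrow CH2 modes are the regime this ratio targets
CH_PEAKS = [
    SpectralPeak(2850, 1.0, 16),
    SpectralPeak(2871, 0.45, 13),
    SpectralPeak(2885, 0.8, 13),
    SpectralPeak(2927, 0.9, 18),
    SpectralPeak(2958, 0.4, 15),
]


class TestAreaRatio:
    def test_equal_width_amplitude_ratio(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(2850, 1.0, 20), SpectralPeak(2885, 0.8, 20)],
            grid=(2700, 3100, 1),
        )
        s, _ = fm.generate_spectrum(d)
        assert fm.area_ratio_2885_2850(s) == pytest.approx(0.8, rel=0.01)

    def test_equal_amplitude_width_ratio(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(2850, 1.0, 20), SpectralPeak(2885, 1.0, 16)],
            grid=(2700, 3100, 1),
        )
        s, _ = fm.generate_spectrum(d)
        assert fm.area_ratio_2885_2850(s) == pytest.approx(0.8, rel=0.01)

    def test_five_peak_noisy_recovery(self):
        errors = []
        analytic = CH_PEAKS[2].area / CH_PEAKS[0].area
        for seed in range(20):
            # noise_sd = 1% of the spectrum maximum (~1.4 with overlap)
            d = SpectrumDesign(peaks=CH_PEAKS, noise_sd=0.014, grid=(2700, 3100, 1),
                               seed=seed)
            s, _ = fm.generate_spectrum(d)
            errors.append(fm.area_ratio_2885_2850(s) / analytic - 1.0)
        assert np.mean(np.abs(errors)) < 0.03

    def test_missing_band_raises(self):
        d = SpectrumDesign(peaks=[SpectralPeak(2850, 1.0, 20)], grid=(2700, 3100, 1))
        s, _ = fm.generate_spectrum(d)
        with pytest.raises(ValueError, match="2885"):
            fm.area_ratio_2885_2850(s)


class TestHalfHeightBandwidth:
    def test_gaussian_closed_form(self):
        d = SpectrumDesign(peaks=[SpectralPeak(1295, 1.0, 14)], grid=(1100, 1500, 1))
        s, _ = fm.generate_spectrum(d)
        assert fm.half_height_bandwidth(s, 1295) == pytest.approx(14.0, abs=0.1)

    def test_lorentzian_closed_form(self):
        d = SpectrumDesign(
            peaks=[SpectralPeak(1295, 1.0, 10, "lorentzian")], grid=(1100, 1500, 1)
        )
        s, _ = fm.generate_spectrum(d)
        assert fm.half_height_bandwidth(s, 1295) == pytest.approx(10.0, abs=0.2)

    def test_sloped_baseline_with_noise(self):
        widths = []
        for seed in range(20):
            d = SpectrumDesign(
                peaks=[SpectralPeak(1295, 1.0, 14)],
                baseline_coeffs=(0.0, 0.0005), noise_sd=0.002,
                grid=(1100, 1500, 1), seed=seed,
            )
            s, _ = fm.generate_spectrum(d)
            widths.append(fm.half_height_bandwidth(s, 1295))
        assert np.mean(widths) == pytest.approx(14.0, rel=0.05)

    def test_no_peak_raises(self):
        w = np.arange(1100.0, 1500.0 + 1)
        s = RamanSpectrum(w, np.linspace(0, 1, w.size))
        with pytest.raises(ValueError, match="local maximum"):
            fm.half_height_bandwidth(s, 1295)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_all_named_ratios_scale_invariant(scale, seed):
    """Every named band ratio is invariant under positive scaling."""
    d = SpectrumDesign(
        peaks=[
            SpectralPeak(2140, 0.3, 20), SpectralPeak(2176, 0.2, 20),
            SpectralPeak(2850, 1.0, 20), SpectralPeak(2935, 0.9, 22),
            SpectralPeak(3012, 0.25, 18),
        ],
        noise_sd=0.003, grid=(1800, 3100, 1), seed=seed,
    )
    s, _ = fm.generate_spectrum(d)
    scaled = RamanSpectrum(s.wavenumbers, scale * s.intensities)
    for num, den in ((2140, 2850), (2176, 2850), (3012, 2850), (2850, 2935)):
        assert abs(fm.band_ratio(s, num, den) - fm.band_ratio(scaled, num, den)) < 1e-12
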