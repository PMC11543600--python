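"""Log-normal line shape, spectrum generation and unmixing recovery."""

import numpy as np
import pytest
from scipy.integrate import quad

from photoblue.spectral import (
    EmissionSpectrum,
    LogNormalComponent,
    SpectralBinning,
    SpectralFitError,
    blue_fraction_series,
    fit_one_component,
    fit_two_component,
    lognormal_shape,
)
from photoblue.synth import (
    PhotoKineticsParams,
    simulate_photoconversion,
    spectral_series_from_trajectory,
    synth_spectrum,
    true_blue_area_fraction,
)


class TestShape:
    def test_peak_value_is_amplitude(self, red_dye):
        assert lognormal_shape(red_dye.lambda_max, red_dye) == pytest.approx(
            red_dye.amplitude, rel=1e-14
        )

    def test_gaussian_limit_half_maximum_at_w_over_2(self):
        # the deviation from amplitude/2 at lambda_max +- w/2 is first order
        # in the asymmetry (ln2 * a), vanishing in the Gaussian limit
        for a, tol in ((1e-4, 1e-4), (1e-6, 1e-6)):
            c = LogNormalComponent(100.0, 650.0, 40.0, a=a)
            for lam in (650.0 - 20.0, 650.0 + 20.0):
                assert lognormal_shape(lam, c) == pytest.approx(50.0, rel=tol)

    def test_zero_outside_support(self):
        c = LogNormalComponent(100.0, 650.0, 40.0, a=0.24)
        # support boundary: 1 + 2a(lam - lmax)/w = 0  =>  lam = lmax - w/(2a)
        boundary = 650.0 - 40.0 / (2 * 0.24)
        assert lognormal_shape(boundary - 1.0, c) == 0.0
        assert lognormal_shape(boundary - 100.0, c) == 0.0

    def test_non_finite_wavelength_rejected(self, red_dye):
        with pytest.raises(ValueError):
            lognormal_shape(np.nan, red_dye)

    @pytest.mark.parametrize("a", [0.05, 0.24, 0.6])
    def test_integral_matches_adaptive_quadrature(self, a):
        c = LogNormalComponent(1.0, 650.0, 45.0, a=a)
        ref, _ = quad(lambda x: lognormal_shape(x, c), 300.0, 1400.0, limit=400)
        grid = np.linspace(300.0, 1400.0, 220_001)
        approx = np.trapezoid(lognormal_shape(grid, c), grid)
        assert np.isfinite(ref) and ref > 0
        assert approx == pytest.approx(ref, rel=1e-6)


class TestSynthSpectrum:
    def test_peak_bin_contains_lambda_max(self, bins16, red_dye):
        s = synth_spectrum([red_dye], bins16)
        i = int(np.argmax(s.counts))
        assert abs(bins16.bin_centers[i] - red_dye.lambda_max) <= bins16.bin_width / 2

    def test_linearity_of_components(self, bins16, red_dye, blue_species):
        both = synth_spectrum([red_dye, blue_species], bins16)
        r = synth_spectrum([red_dye], bins16)
        b = synth_spectrum([blue_species], bins16)
        np.testing.assert_allclose(both.counts, r.counts + b.counts, rtol=1e-12)

    def test_poisson_noise_scale(self, bins16):
        # broad component spreading ~1e6 counts across all bins: relative
        # Poisson deviations stay below 1 % in nearly every bin
        broad = LogNormalComponent(1.0, 668.0, 300.0, a=0.24)
        clean = synth_spectrum([broad], bins16, total_counts=1e6)
        noisy = synth_spectrum([broad], bins16, total_counts=1e6, noise_seed=7)
        rel = np.abs(noisy.counts - clean.counts) / clean.counts
        assert np.sum(rel < 0.01) >= 14

    def test_zero_width_bins_rejected(self):
        with pytest.raises(ValueError):
            SpectralBinning(np.array([600.0, 612.5]), 0.0)


class TestOneComponentFit:
    def test_noiseless_round_trip(self, bins16, red_dye):
        s = synth_spectrum([red_dye], bins16)
        c = fit_one_component(s)
        assert c.lambda_max == pytest.approx(red_dye.lambda_max, abs=0.01)
        assert c.w == pytest.approx(red_dye.w, abs=0.1)

    def test_single_nonzero_bin_rejected(self, bins16):
        counts = np.zeros(16)
        counts[8] = 1000.0
        with pytest.raises(SpectralFitError):
            fit_one_component(EmissionSpectrum(bins16, counts))

    def test_poisson_peak_recovery_calibration(self, bins16, red_dye):
        # 100-seed Monte Carlo at 1e5 photons, frozen regression bound
        hits = 0
        for seed in range(100):
            s = synth_spectrum([red_dye], bins16, total_counts=1e5, noise_seed=seed)
            c = fit_one_component(s)
            hits += abs(c.lambda_max - red_dye.lambda_max) < 1.0
        assert hits >= 95

    def test_scaling_counts_scales_amplitude_only(self, bins16, red_dye):
        s1 = synth_spectrum([red_dye], bins16)
        s2 = EmissionSpectrum(bins16, s1.counts * 37.0)
        c1 = fit_one_component(s1)
        c2 = fit_one_component(s2)
        assert c2.amplitude == pytest.approx(37.0 * c1.amplitude, rel=1e-6)
        assert c2.lambda_max == pytest.approx(c1.lambda_max, rel=1e-8)
        assert c2.w == pytest.approx(c1.w, rel=1e-6)


class TestTwoComponentFit:
    def test_absent_species_gives_near_zero_fraction(self, bins16, red_dye):
        s = synth_spectrum([red_dye], bins16)
        c1 = fit_one_component(s)
        res = fit_two_component(s, c1)
        assert res.area_fractions[1] < 0.02

    def test_recovers_blue_shift_and_fraction(self, bins16, red_dye, blue_species):
        # equal-area mixture with a 22 nm shift: the strong-photoblueing regime
        area_r = synth_spectrum([red_dye], bins16).total_counts
        area_b = synth_spectrum([blue_species], bins16).total_counts
        blue = LogNormalComponent(
            blue_species.amplitude * area_r / area_b,
            blue_species.lambda_max,
            blue_species.w,
        )
        c1 = fit_one_component(synth_spectrum([red_dye], bins16))
        res = fit_two_component(synth_spectrum([red_dye, blue], bins16), c1)
        shift = c1.lambda_max - res.components[1].lambda_max
        assert shift == pytest.approx(22.0, abs=1.0)
        assert res.area_fractions[1] == pytest.approx(0.5, abs=0.03)

    def test_fractions_sum_to_one(self, bins16, red_dye, blue_species):
        c1 = fit_one_component(synth_spectrum([red_dye], bins16))
        res = fit_two_component(synth_spectrum([red_dye, blue_species], bins16), c1)
        assert res.area_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.area_fractions >= 0) and np.all(res.area_fractions <= 1)

    def test_zero_bounded_component2_reproduces_one_component_residual(
        self, bins16, red_dye, rng
    ):
        s = synth_spectrum([red_dye], bins16, total_counts=5e4, noise_seed=3)
        c1 = fit_one_component(s)
        from photoblue.spectral import estimate_background, lognormal_shape as shape

        bg = estimate_background(s)
        counts = np.clip(s.counts - bg, 0, None)
        one_rms = float(
            np.sqrt(np.mean((shape(bins16.bin_centers, c1) * bins16.bin_width - counts) ** 2))
        )
        res = fit_two_component(s, c1, max_amplitude2=0.0)
        assert res.residual_rms == pytest.approx(one_rms, rel=1e-6)


class TestBlueFractionSeries:
    def test_static_series_stays_near_zero(self, bins16, red_dye):
        initial = synth_spectrum([red_dye], bins16, total_counts=2e5, noise_seed=1)
        series = [
            synth_spectrum([red_dye], bins16, total_counts=2e5, noise_seed=10 + i)
            for i in range(4)
        ]
        fr = blue_fraction_series(series, initial)
        assert np.all(fr < 0.02)

    def test_recovers_kinetics_driven_fractions(self, bins16, red_dye, blue_species):
        traj = simulate_photoconversion(
            PhotoKineticsParams(k_blue=0.03, k_bleach_red=0.05, k_bleach_blue=0.01), 17
        )
        initial, series = spectral_series_from_trajectory(
            traj, red_dye, blue_species, bins16, total_counts_initial=2e5, noise_seed=5
        )
        fr = blue_fraction_series(series, initial)
        truth = true_blue_area_fraction(traj, red_dye, blue_species, bins16)
        assert np.max(np.abs(fr - truth)) < 0.05
        # monotone kinetics give a monotone fraction series (small tolerance)
        assert np.all(np.diff(fr) > -0.03)

    def test_binning_mismatch_rejected(self, bins16, red_dye):
        other = SpectralBinning.default16(start_nm=500.0)
        initial = synth_spectrum([red_dye], bins16)
        odd = synth_spectrum([red_dye], other)
        with pytest.raises(ValueError):
            blue_fraction_series([odd], initial)
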