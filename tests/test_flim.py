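"""Decay generation, lifetime estimators, antibody-quenching mechanism."""

import numpy as np
import pytest

from photoblue.flim import estimate_lifetime, lifetime_series
from photoblue.synth import (
    AntibodyEnsembleConfig,
    DecayHistogram,
    antibody_decay_series,
    antibody_ensemble_expectation,
    simulate_antibody_flim,
    synth_decay,
    truncated_exponential_mean,
)

PERIOD = 25.0


def analytic_histogram(tau, n_photons=1e6, n_bins=250, background_fraction=0.0):
    """Noise-free histogram: expected counts of a wrapped exponential."""
    edges = np.linspace(0.0, PERIOD, n_bins + 1)
    norm = 1.0 - np.exp(-PERIOD / tau)
    cdf = (1.0 - np.exp(-edges / tau)) / norm
    sig = np.diff(cdf) * n_photons * (1 - background_fraction)
    bg = n_photons * background_fraction / n_bins
    return DecayHistogram(edges, sig + bg)


class TestSynthDecay:
    def test_histogram_mean_matches_truncated_exponential(self):
        d = synth_decay(3.0, 1_000_000, seed=1)
        mean = float((d.counts * d.bin_centers).sum() / d.counts.sum())
        assert mean == pytest.approx(truncated_exponential_mean(3.0, PERIOD), rel=0.005)

    def test_empty_decay_flagged(self):
        d = synth_decay(3.0, 0, seed=1)
        assert d.is_empty
        res = estimate_lifetime(d)
        assert not res.converged

    def test_determinism_under_seed(self):
        d1 = synth_decay(2.5, 10_000, irf_sigma=0.2, background_fraction=0.1, seed=9)
        d2 = synth_decay(2.5, 10_000, irf_sigma=0.2, background_fraction=0.1, seed=9)
        np.testing.assert_array_equal(d1.counts, d2.counts)

    def test_tau_beyond_period_rejected(self):
        with pytest.raises(ValueError):
            synth_decay(30.0, 1000, period=PERIOD)


class TestEstimators:
    @pytest.mark.parametrize("method", ["mean_arrival", "mono_exp_fit"])
    def test_noiseless_round_trip(self, method):
        res = estimate_lifetime(analytic_histogram(3.5), method=method)
        assert res.converged
        assert res.tau == pytest.approx(3.5, rel=0.02)

    def test_uniform_histogram_flagged(self):
        edges = np.linspace(0.0, PERIOD, 251)
        flat = DecayHistogram(edges, np.full(250, 400))
        for method in ("mean_arrival", "mono_exp_fit"):
            res = estimate_lifetime(flat, method=method)
            assert not res.converged
            assert np.isnan(res.tau)

    def test_fit_with_background(self):
        d = synth_decay(3.5, 100_000, background_fraction=0.10, seed=4)
        res = estimate_lifetime(d, method="mono_exp_fit")
        assert res.converged
        assert res.tau == pytest.approx(3.5, rel=0.03)

    def test_mean_arrival_linear_in_photon_mixtures(self):
        # pooling two decays gives the photon-weighted mean arrival time
        d1 = analytic_histogram(2.0, n_photons=3e5)
        d2 = analytic_histogram(4.0, n_photons=3e5)
        pooled = DecayHistogram(d1.bin_edges, d1.counts + d2.counts)
        res = estimate_lifetime(pooled, background=0.0)
        expected_mean = 0.5 * (
            truncated_exponential_mean(2.0, PERIOD) + truncated_exponential_mean(4.0, PERIOD)
        )
        assert truncated_exponential_mean(res.tau, PERIOD) == pytest.approx(
            expected_mean, rel=1e-3
        )

    def test_invariance_under_count_scaling(self):
        d = analytic_histogram(3.0, n_photons=1e5)
        scaled = DecayHistogram(d.bin_edges, d.counts * 7)
        for method, tol in (("mean_arrival", 1e-12), ("mono_exp_fit", 1e-3)):
            t1 = estimate_lifetime(d, method=method).tau
            t2 = estimate_lifetime(scaled, method=method).tau
            assert t2 == pytest.approx(t1, rel=tol)

    def test_truncation_correction_wins_near_long_lifetimes(self):
        tau = PERIOD / 5.0
        d = analytic_histogram(tau, n_photons=1e6)
        naive = float((d.counts * d.bin_centers).sum() / d.counts.sum())
        corrected = estimate_lifetime(d).tau
        assert abs(naive - tau) / tau > 0.01  # naive visibly underestimates
        assert corrected == pytest.approx(tau, rel=0.005)
        # for tau << period the two agree closely
        short = analytic_histogram(0.8, n_photons=1e6)
        naive_s = float((short.counts * short.bin_centers).sum() / short.counts.sum())
        assert estimate_lifetime(short).tau == pytest.approx(naive_s, rel=1e-3)


class TestAntibodyMechanism:
    def test_single_dye_lifetime_flat_intensity_decays(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=1, seed=2)
        sim = simulate_antibody_flim(cfg, 10)
        live = np.isfinite(sim.mean_lifetime)
        assert np.allclose(sim.mean_lifetime[live], cfg.tau_unquenched)
        exp = antibody_ensemble_expectation(cfg, 10)
        assert np.all(np.diff(exp.total_intensity) <= 1e-12)

    def test_two_dye_lifetime_rises(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=2, seed=3)
        exp = antibody_ensemble_expectation(cfg, 15)
        assert np.all(np.diff(exp.mean_lifetime) >= -1e-12)
        assert exp.mean_lifetime[-1] - exp.mean_lifetime[0] > 1.0

    def test_intensity_rises_then_falls(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=2, quenched_yield=0.3, seed=1)
        exp = antibody_ensemble_expectation(cfg, 40)
        peak = int(np.argmax(exp.total_intensity))
        assert 0 < peak < 39
        assert exp.total_intensity[peak] > exp.total_intensity[0]
        assert exp.total_intensity[-1] < exp.total_intensity[0]

    def test_monte_carlo_matches_enumeration(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=2, n_antibodies=60_000, seed=8)
        sim = simulate_antibody_flim(cfg, 10)
        exp = antibody_ensemble_expectation(cfg, 10)
        np.testing.assert_allclose(
            sim.mean_lifetime, exp.mean_lifetime, rtol=0.01
        )
        np.testing.assert_allclose(
            sim.total_intensity / cfg.n_antibodies, exp.total_intensity, rtol=0.02
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AntibodyEnsembleConfig(dyes_per_antibody=0)
        with pytest.raises(ValueError):
            AntibodyEnsembleConfig(tau_quenched=4.0, tau_unquenched=3.5)


class TestLifetimeSeries:
    def test_single_dye_series_is_flat(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=1, n_antibodies=4000, seed=5)
        decays = antibody_decay_series(cfg, 8)
        series = lifetime_series(decays)
        live = np.isfinite(series.delta_tau)
        assert np.all(np.abs(series.delta_tau[live]) < 0.08)

    def test_two_dye_series_rises_above_one_ns(self):
        cfg = AntibodyEnsembleConfig(dyes_per_antibody=2, n_antibodies=4000, seed=6)
        decays = antibody_decay_series(cfg, 15)
        series = lifetime_series(decays)
        assert series.delta_tau[-1] > 1.0
        exp = antibody_ensemble_expectation(cfg, 15)
        expected_rise = exp.mean_lifetime[-1] - exp.mean_lifetime[0]
        assert series.delta_tau[-1] == pytest.approx(expected_rise, abs=0.15)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            lifetime_series([analytic_histogram(3.0)])
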