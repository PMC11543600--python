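"""Brownian-diffusion trace generator: statics, determinism, Poisson nulls."""

import numpy as np
import pytest
from scipy import stats

from photoblue.synth import TraceSimConfig, simulate_fcs_trace


def pinned_config(seed=0, n_bins=5000, rate=30_000.0, T=0.0):
    return TraceSimConfig(
        n_molecules=1,
        diffusion_coeff=0.0,
        counts_per_molecule=rate,
        bin_time=1e-4,
        duration=n_bins * 1e-4,
        T=T,
        seed=seed,
    )


def center_position(cfg):
    return np.full((cfg.n_molecules, 2), cfg.box_size / 2.0)


def test_static_emitter_mean_rate():
    cfg = pinned_config(seed=3, n_bins=20_000)
    trace = simulate_fcs_trace(cfg, initial_positions=center_position(cfg))
    expected = cfg.counts_per_molecule * cfg.bin_time
    assert trace.counts.mean() == pytest.approx(expected, rel=0.02)


def test_same_seed_reproduces_trace_exactly():
    cfg = TraceSimConfig(duration=1.0, seed=42, T=0.1)
    t1 = simulate_fcs_trace(cfg)
    t2 = simulate_fcs_trace(cfg)
    np.testing.assert_array_equal(t1.counts, t2.counts)


def test_different_seed_changes_trace():
    t1 = simulate_fcs_trace(TraceSimConfig(duration=1.0, seed=1))
    t2 = simulate_fcs_trace(TraceSimConfig(duration=1.0, seed=2))
    assert not np.array_equal(t1.counts, t2.counts)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"omega0": 900.0},  # beam does not fit the box
        {"T": 1.0},
        {"duration": 1.5e-4},  # fewer than 2 bins
        {"n_molecules": 0},
    ],
)
def test_unphysical_config_rejected(kwargs):
    with pytest.raises(ValueError):
        TraceSimConfig(**kwargs)


def test_pinned_emitter_counts_are_poisson():
    # chi-square goodness of fit of the marginal count distribution against
    # Poisson with the configured mean; the distribution is invariant under
    # index shuffling, so this checks the per-bin law itself
    rejections = 0
    for seed in range(20):
        cfg = pinned_config(seed=seed, n_bins=5000, rate=30_000.0)
        trace = simulate_fcs_trace(cfg, initial_positions=center_position(cfg))
        lam = cfg.counts_per_molecule * cfg.bin_time
        kmax = int(stats.poisson.ppf(0.9999, lam))
        clipped = np.minimum(trace.counts, kmax + 1)  # last category = ">= kmax+1"
        observed = np.bincount(clipped, minlength=kmax + 2).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 2), lam)
        expected[-1] = 1.0 - expected[:-1].sum()
        expected *= trace.counts.size
        # pool sparse categories so chi-square is valid
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        _, p = stats.chisquare(obs, exp)
        rejections += p < 0.01
    assert rejections <= 2


def test_triplet_reduces_mean_rate_by_dark_fraction():
    cfg0 = pinned_config(seed=5, n_bins=20_000, T=0.0)
    cfg1 = pinned_config(seed=5, n_bins=20_000, T=0.3)
    t0 = simulate_fcs_trace(cfg0, initial_positions=center_position(cfg0))
    t1 = simulate_fcs_trace(cfg1, initial_positions=center_position(cfg1))
    assert t1.counts.mean() / t0.counts.mean() == pytest.approx(0.7, abs=0.03)


def test_effective_n_formula():
    cfg = TraceSimConfig()
    expected = cfg.n_molecules * np.pi * cfg.omega0**2 / cfg.box_size**2
    assert cfg.effective_n == pytest.approx(expected)
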