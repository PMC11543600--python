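"""Synthetic binned emission spectra and illumination time series."""

from __future__ import annotations

import numpy as np

from ..spectral import (
    EmissionSpectrum,
    LogNormalComponent,
    SpectralBinning,
    expected_counts,
)
from .kinetics import StateTrajectory

__all__ = ["synth_spectrum", "spectral_series_from_trajectory", "true_blue_area_fraction"]


def synth_spectrum(
    components,
    bins: SpectralBinning,
    noise_seed: int | None = None,
    total_counts: float | None = None,
    excitation_nm: float | None = None,
) -> EmissionSpectrum:
    """Generate a binned spectrum from a sum of log-normal components.

    Per-bin expected intensity is the continuous line shape integrated over
    the bin by the midpoint rule.  When ``total_counts`` is given the
    expected spectrum is rescaled to that total (preserving the components'
    relative areas).  With ``noise_seed`` set, per-bin counts are drawn
    Poisson; otherwise the noiseless expectation is returned.
    """
    components = list(components)
    if not components:
        raise ValueError("need at least one component")
    mu = expected_counts(components, bins)
    if total_counts is not None:
        s = mu.sum()
        if s <= 0:
            raise ValueError("cannot rescale an all-zero spectrum to total_counts")
        mu = mu * (float(total_counts) / s)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        counts = rng.poisson(mu).astype(float)
    else:
        counts = mu
    return EmissionSpectrum(bins, counts, excitation_nm=excitation_nm)


def spectral_series_from_trajectory(
    traj: StateTrajectory,
    red: LogNormalComponent,
    blue: LogNormalComponent,
    bins: SpectralBinning,
    total_counts_initial: float | None = None,
    emission_weight_blue: float = 1.0,
    noise_seed: int | None = None,
) -> tuple[EmissionSpectrum, list[EmissionSpectrum]]:
    """Spectra of a photoconverting population over illumination frames.

    At every frame the red component's amplitude is scaled by ``f_red`` and
    the blue-shifted component's by ``f_blue * emission_weight_blue`` (the
    photoblued species' relative emission strength under the recording
    excitation).  Returns the frame-0 (initial) spectrum and the full series.
    """
    if total_counts_initial is not None and total_counts_initial <= 0:
        raise ValueError("total_counts_initial must be > 0")
    scale = 1.0
    if total_counts_initial is not None:
        base = synth_spectrum([red], bins).total_counts
        if base <= 0:
            raise ValueError("red component has no area in the recorded window")
        scale = float(total_counts_initial) / base
    seeds = _spawn_seeds(noise_seed, traj.n_frames)
    series: list[EmissionSpectrum] = []
    for i in range(traj.n_frames):
        amp_r = red.amplitude * float(traj.f_red[i]) * scale
        amp_b = blue.amplitude * float(traj.f_blue[i]) * emission_weight_blue * scale
        comps = []
        if amp_r > 0:
            comps.append(LogNormalComponent(amp_r, red.lambda_max, red.w, red.a))
        if amp_b > 0:
            comps.append(LogNormalComponent(amp_b, blue.lambda_max, blue.w, blue.a))
        if not comps:
            comps = [LogNormalComponent(0.0, red.lambda_max, red.w, red.a)]
        series.append(synth_spectrum(comps, bins, noise_seed=seeds[i]))
    return series[0], series


def true_blue_area_fraction(
    traj: StateTrajectory,
    red: LogNormalComponent,
    blue: LogNormalComponent,
    bins: SpectralBinning,
    emission_weight_blue: float = 1.0,
) -> np.ndarray:
    """Ground-truth blue emission-area fraction per frame of a series."""
    area_r = synth_spectrum([red], bins).total_counts
    area_b = synth_spectrum([blue], bins).total_counts
    num = traj.f_blue * emission_weight_blue * area_b
    den = traj.f_red * area_r + num
    out = np.zeros(traj.n_frames)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _spawn_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n)]
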