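"""FCS model functions for 2D anomalous diffusion with triplet kinetics.

The autocorrelation of a membrane (2D) diffusion measurement is

    G(tau) = (1/N) * (1 + (tau/tau_D)**alpha)**-1

with N the average number of molecules in the observation spot, tau_D the
average transit time and alpha the anomaly parameter.  Triplet (dark-state)
blinking multiplies this by (1 - T + T exp(-tau/tau_triplet)) with T the
stationary triplet fraction.  G(0) = 1/N in both models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FCSModelParams", "model_diffusion_2d", "model_with_triplet"]


@dataclass(frozen=True)
class FCSModelParams:
    """Parameters of the triplet-extended 2D diffusion model."""

    N: float
    tau_D: float
    alpha: float = 1.0
    T: float = 0.0
    tau_triplet: float = 5e-6

    def __post_init__(self) -> None:
        if not (self.N > 0):
            raise ValueError("N must be > 0")
        if not (self.tau_D > 0):
            raise ValueError("tau_D must be > 0")
        if not (0 < self.alpha <= 2):
            raise ValueError("alpha must be in (0, 2]")
        if not (0 <= self.T < 1):
            raise ValueError("T must be in [0, 1)")
        if not (self.tau_triplet > 0):
            raise ValueError("tau_triplet must be > 0")


def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0) or not np.all(np.isfinite(tau)):
        raise ValueError("lag times must be finite and >= 0")
    return tau


def model_diffusion_2d(tau, N: float, tau_D: float, alpha: float = 1.0):
    """G(tau) of free/anomalous 2D diffusion through a Gaussian spot."""
    if N <= 0 or tau_D <= 0 or not (0 < alpha <= 2):
        raise ValueError("invalid model parameters")
    tau = _check_tau(tau)
    g = (1.0 / N) / (1.0 + (tau / tau_D) ** alpha)
    return float(g) if g.ndim == 0 else g


def model_with_triplet(tau, params: FCSModelParams):
    """Diffusion model multiplied by the triplet blinking factor."""
    tau = _check_tau(tau)
    g = model_diffusion_2d(tau, params.N, params.tau_D, params.alpha)
    trip = 1.0 - params.T + params.T * np.exp(-tau / params.tau_triplet)
    out = g * trip
    return float(out) if np.ndim(out) == 0 else out
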