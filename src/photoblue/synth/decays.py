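"""Synthetic TCSPC decay histograms.

Photon arrival times are exponential with the fluorescence lifetime, wrapped
into one excitation period (pulsed excitation; the default 25 ns period
corresponds to a 40 MHz repetition rate), jittered by a Gaussian instrument
response, and mixed with a uniform background.  Wrapping an exponential into
the period yields exactly the exponential truncated at the period, so the
closed-form truncated-exponential mean applies to the noiseless histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DecayHistogram", "synth_decay", "sample_arrival_times"]

DEFAULT_PERIOD_NS = 25.0  # one cycle at 40 MHz pulsed excitation


@dataclass(frozen=True)
class DecayHistogram:
    """TCSPC arrival-time histogram over one excitation period."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("need >= 2 bins")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bins must be uniform and increasing")
        if counts.shape != (edges.size - 1,):
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def period(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total_photons == 0


def sample_arrival_times(
    rng: np.random.Generator,
    tau: float,
    n_photons: int,
    period: float,
    irf_sigma: float = 0.0,
) -> np.ndarray:
    """Exponential arrival times wrapped into one period, with IRF jitter."""
    t = rng.exponential(tau, size=n_photons)
    if irf_sigma > 0:
        t = t + rng.normal(0.0, irf_sigma, size=n_photons)
    return np.mod(t, period)


def synth_decay(
    tau: float,
    n_photons: int,
    period: float = DEFAULT_PERIOD_NS,
    irf_sigma: float = 0.0,
    background_fraction: float = 0.0,
    seed: int | None = None,
    n_bins: int = 250,
) -> DecayHistogram:
    """Generate a TCSPC histogram for a mono-exponential decay.

    ``background_fraction`` of the photons are uniform over the period.
    ``tau`` must be below ``period`` (otherwise wrap-around dominates and the
    histogram is nearly flat).  Deterministic under a fixed seed.
    """
    if not (0 < tau < period):
        raise ValueError(f"tau must satisfy 0 < tau < period ({period} ns), got {tau}")
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    if not (0 <= background_fraction < 1):
        raise ValueError("background_fraction must be in [0, 1)")
    if irf_sigma < 0:
        raise ValueError("irf_sigma must be >= 0")
    edges = np.linspace(0.0, period, n_bins + 1)
    if n_photons == 0:
        return DecayHistogram(edges, np.zeros(n_bins, dtype=np.int64))
    rng = np.random.default_rng(seed)
    n_bg = rng.binomial(n_photons, background_fraction) if background_fraction > 0 else 0
    t_sig = sample_arrival_times(rng, tau, n_photons - n_bg, period, irf_sigma)
    t_bg = rng.uniform(0.0, period, size=n_bg)
    counts, _ = np.histogram(np.concatenate([t_sig, t_bg]), bins=edges)
    return DecayHistogram(edges, counts.astype(np.int64))


def truncated_exponential_mean(tau: float, period: float) -> float:
    """Mean of an exponential(tau) truncated (wrapped) at ``period``."""
    with np.errstate(over="ignore"):
        return float(tau - period / np.expm1(period / tau))
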