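"""Fluctuating-intensity traces from 2D Brownian diffusers.

Emulates a point-detector FCS measurement on a supported lipid bilayer:
molecules diffuse in a periodic 2D box, are detected through a Gaussian
observation profile exp(-2 r^2 / omega0^2) centred in the box, blink through
a two-state (bright/triplet) Markov chain, and per-bin photon counts are
drawn Poisson.  The theoretical transit time is tau_D = omega0^2 / (4 D) and
the effective mean occupancy of the observation area is

    N_eff = concentration * pi * omega0^2
          = n_molecules * pi * omega0^2 / box_size^2

(the standard 2D Gaussian effective area A_eff = (int W)^2 / int W^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TraceSimConfig", "IntensityTrace", "simulate_fcs_trace"]


@dataclass(frozen=True)
class IntensityTrace:
    """Binned photon-count time trace."""

    counts: np.ndarray
    bin_time: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("trace needs >= 2 bins")
        if self.bin_time <= 0:
            raise ValueError("bin_time must be > 0")
        if not np.all(np.isfinite(counts.astype(float))) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_time

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate in Hz."""
        return float(self.counts.mean() / self.bin_time)


@dataclass(frozen=True)
class TraceSimConfig:
    """Parameters of the Brownian-diffusion / triplet-blinking simulation.

    Units: lengths in nm, times in s, diffusion in um^2/s.  The default
    10 s acquisition mirrors a typical point-FCS measurement; ``T`` and
    ``tau_triplet`` set the stationary triplet (dark) fraction and its
    correlation time.
    """

    n_molecules: int = 135
    omega0: float = 240.0
    diffusion_coeff: float = 1.0
    box_size: float = 3000.0
    T: float = 0.0
    tau_triplet: float = 5e-6
    counts_per_molecule: float = 30_000.0
    bin_time: float = 1e-4
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.omega0 <= 0 or self.box_size <= 0:
            raise ValueError("omega0 and box_size must be > 0")
        if self.omega0 >= self.box_size / 4:
            raise ValueError("omega0 must be < box_size / 4 (beam must fit the box)")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if not (0 <= self.T < 1):
            raise ValueError("triplet fraction T must be in [0, 1)")
        if self.tau_triplet <= 0:
            raise ValueError("tau_triplet must be > 0")
        if self.counts_per_molecule < 0 or self.bin_time <= 0 or self.duration <= 0:
            raise ValueError("counts_per_molecule, bin_time, duration must be positive")
        n = self.duration / self.bin_time
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("duration/bin_time must be an integer number of bins >= 2")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    @property
    def effective_n(self) -> float:
        """Expected FCS amplitude parameter N for this configuration."""
        return self.n_molecules * np.pi * self.omega0**2 / self.box_size**2

    @property
    def tau_d(self) -> float:
        """Theoretical transit time omega0^2 / (4 D) in seconds."""
        d_nm2 = self.diffusion_coeff * 1e6  # um^2/s -> nm^2/s
        return self.omega0**2 / (4.0 * d_nm2)

    @property
    def effective_rate_per_molecule(self) -> float:
        """Mean detected rate per effective molecule, counts_per_molecule / 2.

        mean_rate = n rho c <W> and N_eff = n rho A_eff give
        Q = c <W> A_eff / (pi omega0^2) = c / 2 for the 2D Gaussian profile.
        """
        return self.counts_per_molecule / 2.0


def _triplet_gate(
    rng: np.random.Generator,
    carry: np.ndarray,
    n_bins: int,
    p_b_given_b: float,
    p_b_given_d: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample bright (1) / dark (0) states for one chunk of bins.

    Uses the exact two-state propagator over one bin.  Vectorised via forced
    transitions: with a single uniform draw u per (bin, molecule), the next
    state is bright if u < p(bright|dark), dark if u >= p(bright|bright), and
    otherwise inherits the previous state (valid since
    p(bright|dark) <= p(bright|bright)); inherited states are resolved by
    propagating the last forced value forward.
    """
    n_mol = carry.size
    u = rng.random((n_bins, n_mol))
    forced_bright = u < p_b_given_d
    forced_dark = u >= p_b_given_b
    is_forced = forced_bright | forced_dark
    values = np.empty((n_bins + 1, n_mol), dtype=np.int8)
    values[0] = carry
    values[1:] = np.where(forced_bright, 1, 0)
    idx = np.where(is_forced, np.arange(1, n_bins + 1)[:, None], 0)
    last = np.maximum.accumulate(idx, axis=0)
    states = values[last, np.arange(n_mol)[None, :]]
    return states, states[-1].copy()


def simulate_fcs_trace(
    cfg: TraceSimConfig, initial_positions: np.ndarray | None = None
) -> IntensityTrace:
    """Simulate a binned photon-count trace for the given configuration.

    ``initial_positions`` (n_molecules, 2) in nm overrides the default
    uniform placement, e.g. to pin a single emitter at the beam centre
    (``box_size/2, box_size/2``).  Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    box = cfg.box_size
    center = box / 2.0
    n_mol = cfg.n_molecules
    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float)
        if pos.shape != (n_mol, 2):
            raise ValueError(f"initial_positions must have shape ({n_mol}, 2)")
        pos = np.mod(pos, box)
    else:
        pos = rng.uniform(0.0, box, size=(n_mol, 2))

    dt = cfg.bin_time
    step_sigma = np.sqrt(2.0 * cfg.diffusion_coeff * 1e6 * dt)  # nm
    flux = cfg.counts_per_molecule * dt

    use_triplet = cfg.T > 0
    if use_triplet:
        decay = np.exp(-dt / cfg.tau_triplet)
        p_b_given_b = (1.0 - cfg.T) + cfg.T * decay
        p_b_given_d = (1.0 - cfg.T) * (1.0 - decay)
        carry = (rng.random(n_mol) >= cfg.T).astype(np.int8)
    else:
        carry = np.ones(n_mol, dtype=np.int8)

    n_bins = cfg.n_bins
    chunk = max(2, min(n_bins, int(4e6 // max(n_mol, 1)) or 2))
    counts = np.empty(n_bins, dtype=np.int64)
    done = 0
    while done < n_bins:
        nb = min(chunk, n_bins - done)
        if step_sigma > 0:
            steps = rng.normal(0.0, step_sigma, size=(nb, n_mol, 2))
            traj = np.mod(pos[None, :, :] + np.cumsum(steps, axis=0), box)
        else:
            traj = np.broadcast_to(pos, (nb, n_mol, 2))
        r2 = (traj[..., 0] - center) ** 2 + (traj[..., 1] - center) ** 2
        w = np.exp(-2.0 * r2 / cfg.omega0**2)
        if use_triplet:
            gate, carry = _triplet_gate(rng, carry, nb, p_b_given_b, p_b_given_d)
            w = w * gate
        mu = flux * w.sum(axis=1)
        counts[done : done + nb] = rng.poisson(mu)
        pos = np.array(traj[-1])
        done += nb
    return IntensityTrace(counts, dt)
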