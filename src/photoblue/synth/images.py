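"""Synthetic two-channel (ratiometric) membrane image stacks.

Emulates GP imaging of a membrane probe: each membrane pixel emits into a
blue band (580-630 nm, I_b) and a red band (650-700 nm, I_r) such that the
per-pixel generalized polarization GP = (I_b - I_r)/(I_b + I_r) equals a
prescribed ground truth.  Photoblueing moves emission from the red band into
the blue band frame by frame, raising the apparent GP; photobleaching scales
the overall intensity.  With an exchangeable probe (replenishment) the
apparent GP stays at the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import PhotoKineticsParams, simulate_photoconversion

__all__ = [
    "TwoChannelImage",
    "TwoChannelImageStack",
    "synth_two_channel_stack",
    "make_membrane_scene",
]


@dataclass(frozen=True)
class TwoChannelImage:
    """One two-channel frame: blue-band and red-band intensities."""

    i_b: np.ndarray
    i_r: np.ndarray
    saturation_value: float = 65535.0
    pixel_size: float = 40.0

    def __post_init__(self) -> None:
        i_b = np.asarray(self.i_b)
        i_r = np.asarray(self.i_r)
        object.__setattr__(self, "i_b", i_b)
        object.__setattr__(self, "i_r", i_r)
        if i_b.shape != i_r.shape:
            raise ValueError(f"channel shapes differ: {i_b.shape} vs {i_r.shape}")
        if np.any(i_b < 0) or np.any(i_r < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class TwoChannelImageStack:
    """Frame-ordered sequence of two-channel images."""

    frames: tuple[TwoChannelImage, ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("stack needs >= 1 frame")
        shape = self.frames[0].i_b.shape
        for f in self.frames:
            if f.i_b.shape != shape:
                raise ValueError("all frames must share one shape")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def saturation_value(self) -> float:
        return self.frames[0].saturation_value

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size


def make_membrane_scene(
    shape: tuple[int, int] = (64, 64),
    stripe: tuple[int, int] = (24, 40),
    gp_value: float = -0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth GP map and membrane mask with a horizontal membrane band."""
    gp_true = np.full(shape, gp_value, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    mask[stripe[0] : stripe[1], :] = True
    return gp_true, mask


def synth_two_channel_stack(
    gp_true: np.ndarray,
    membrane_mask: np.ndarray,
    kinetics: PhotoKineticsParams,
    n_frames: int,
    counts: float = 500.0,
    saturation: float = 65535.0,
    seed: int | None = None,
    background_counts: float = 5.0,
    pixel_size: float = 40.0,
) -> TwoChannelImageStack:
    """Generate an illumination series of two-channel membrane images.

    ``counts`` is the expected summed (I_b + I_r) signal per membrane pixel
    in frame 0.  Per frame t with survival s = f_red + f_blue and converted
    fraction phi = f_blue / s, a fraction phi of the red-band emission is
    moved to the blue band, so for noiseless data the apparent per-pixel GP
    is gp + phi (1 - gp) >= gp.  With ``seed`` set, Poisson shot noise is
    applied and counts are clipped at ``saturation``; with ``seed=None`` the
    exact expected intensities are returned (real-valued).
    """
    gp_true = np.asarray(gp_true, dtype=float)
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if gp_true.shape != membrane_mask.shape:
        raise ValueError("gp_true and membrane_mask shapes must match")
    if np.any(np.abs(gp_true) > 1):
        raise ValueError("gp_true values must lie in [-1, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    traj = simulate_photoconversion(kinetics, n_frames - 1)
    rng = np.random.default_rng(seed) if seed is not None else None

    b_weight = 0.5 * (1.0 + gp_true)
    r_weight = 0.5 * (1.0 - gp_true)
    frames = []
    for t in range(n_frames):
        s = float(traj.f_red[t] + traj.f_blue[t])
        phi = float(traj.f_blue[t] / s) if s > 0 else 0.0
        ib = np.full(gp_true.shape, float(background_counts))
        ir = np.full(gp_true.shape, float(background_counts))
        ib[membrane_mask] = s * counts * (b_weight + phi * r_weight)[membrane_mask]
        ir[membrane_mask] = s * counts * ((1.0 - phi) * r_weight)[membrane_mask]
        if rng is not None:
            ib = np.minimum(rng.poisson(ib), saturation).astype(float)
            ir = np.minimum(rng.poisson(ir), saturation).astype(float)
        frames.append(TwoChannelImage(ib, ir, saturation_value=saturation, pixel_size=pixel_size))
    return TwoChannelImageStack(tuple(frames))
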