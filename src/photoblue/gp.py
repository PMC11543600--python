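"""Ratiometric generalized-polarization (GP) image analysis.

Membrane lipid packing is read out from the spectral balance of an
environment-sensitive probe recorded in two emission bands, blue
(580-630 nm, I_b) and red (650-700 nm, I_r):

    GP = (I_b - I_r) / (I_b + I_r)

per pixel, averaged over the membrane mask.  Masking keeps only pixels whose
summed intensity exceeds a fraction of the image maximum and excludes
saturated pixels.  Over an illumination series the mask from frame 0 is
reused so bleaching-driven mask shrinkage cannot bias the time course; the
reported series is the per-frame mean GP and its change relative to frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth.images import TwoChannelImage, TwoChannelImageStack

__all__ = [
    "GPMap",
    "GPTimeSeries",
    "gp_pixel",
    "membrane_mask",
    "gp_map",
    "gp_change_series",
]

DEFAULT_THRESHOLD_FRACTION = 0.2


def gp_pixel(i_b, i_r):
    """Per-pixel GP; NaN where both channels are zero (undefined)."""
    i_b = np.asarray(i_b, dtype=float)
    i_r = np.asarray(i_r, dtype=float)
    if np.any(i_b < 0) or np.any(i_r < 0):
        raise ValueError("intensities must be non-negative")
    total = i_b + i_r
    with np.errstate(invalid="ignore", divide="ignore"):
        gp = np.where(total > 0, (i_b - i_r) / np.where(total > 0, total, 1.0), np.nan)
    return float(gp) if gp.ndim == 0 else gp


def membrane_mask(
    img: TwoChannelImage, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> np.ndarray:
    """Membrane pixels: bright enough in summed intensity, not saturated.

    A pixel is included iff I_b + I_r >= threshold_fraction * max(I_b + I_r)
    and both channels are below the saturation value.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    total = np.asarray(img.i_b, dtype=float) + np.asarray(img.i_r, dtype=float)
    unsat = (img.i_b < img.saturation_value) & (img.i_r < img.saturation_value)
    return (total >= threshold_fraction * total.max()) & unsat


@dataclass(frozen=True)
class GPMap:
    """Per-pixel GP restricted to a mask, with the ROI mean."""

    gp: np.ndarray
    mask: np.ndarray
    mean_gp: float
    n_pixels_used: int

    @property
    def valid(self) -> bool:
        return self.n_pixels_used > 0 and np.isfinite(self.mean_gp)


def gp_map(img: TwoChannelImage, mask: np.ndarray) -> GPMap:
    """GP of every masked pixel and the unweighted mask mean.

    Pixels with zero summed intensity are undefined (NaN) and excluded from
    the mean.  An empty mask yields a flagged (invalid) map, never an
    exception, so series code can propagate the condition.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.i_b.shape:
        raise ValueError("mask shape must match image")
    gp = np.full(img.i_b.shape, np.nan)
    gp[mask] = gp_pixel(np.asarray(img.i_b)[mask], np.asarray(img.i_r)[mask])
    used = mask & np.isfinite(gp)
    n = int(used.sum())
    mean = float(gp[used].mean()) if n else float("nan")
    return GPMap(gp=gp, mask=mask, mean_gp=mean, n_pixels_used=n)


@dataclass(frozen=True)
class GPTimeSeries:
    """Mean GP per illumination frame and its change vs. frame 0."""

    frames: np.ndarray
    mean_gp: np.ndarray
    delta_gp: np.ndarray
    n_pixels: np.ndarray


def gp_change_series(
    stack: TwoChannelImageStack,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> GPTimeSeries:
    """Mean-GP time course over an illumination series.

    The membrane mask is computed on frame 0 and reused for every frame.
    """
    if stack.n_frames < 2:
        raise ValueError("need >= 2 frames for a series")
    mask0 = membrane_mask(stack.frames[0], threshold_fraction)
    if not mask0.any():
        raise ValueError("frame-0 membrane mask is empty")
    means = np.empty(stack.n_frames)
    ns = np.empty(stack.n_frames, dtype=int)
    for t, frame in enumerate(stack.frames):
        m = gp_map(frame, mask0)
        means[t] = m.mean_gp
        ns[t] = m.n_pixels_used
    return GPTimeSeries(
        frames=np.arange(stack.n_frames),
        mean_gp=means,
        delta_gp=means - means[0],
        n_pixels=ns,
    )
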