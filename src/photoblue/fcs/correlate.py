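"""Multi-tau autocorrelation of photon-count traces.

The normalized fluctuation autocorrelation

    G(tau) = <dI(t) dI(t+tau)> / <I>^2

is evaluated on a quasi-logarithmic lag grid: the first 2m lags at the raw
bin resolution, then m lags per octave on progressively pairwise-coarsened
(block-averaged) copies of the trace.  Symmetric normalization is used: at
each lag the two overlapping segments are normalized by their own means,

    G(k) = <c[t] c[t+k]> / (<c[t]> <c[t+k]>) - 1 ,

which removes the bias from slow drifts at long lags.  Per-lag standard
errors are optionally estimated by splitting the trace into equal segments,
correlating each and taking the standard error across segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..synth.trace import IntensityTrace

__all__ = ["CorrelationCurve", "correlate_multi_tau", "multi_tau_lag_grid"]


@dataclass(frozen=True)
class CorrelationCurve:
    """Autocorrelation curve on a multi-tau lag grid.

    ``lag_bins`` and ``levels`` record, for each lag, the lag in units of
    raw bins and the coarsening level (block size ``2**level``) it was
    computed at; they define the estimator exactly and allow independent
    re-evaluation.
    """

    lags: np.ndarray
    G: np.ndarray
    mean_rate: float
    stderr: np.ndarray | None = None
    lag_bins: np.ndarray | None = None
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", g)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValueError("lags and G must be equal-length 1D arrays")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(g)):
            raise ValueError("G must be finite")
        if self.stderr is not None:
            se = np.asarray(self.stderr, dtype=float)
            object.__setattr__(self, "stderr", se)
            if se.shape != lags.shape:
                raise ValueError("stderr must match lags")

    @property
    def n_lags(self) -> int:
        return int(self.lags.size)


def multi_tau_lag_grid(n_bins: int, m: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Lag grid (in raw-bin units) and coarsening level per lag.

    Level 0 holds lags 1..2m; level L >= 1 holds lags (m+1..2m) * 2**L.
    Octaves are added while the coarsened trace retains at least 8
    overlapping pairs at the largest lag.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    lag_bins: list[int] = []
    levels: list[int] = []
    level = 0
    while True:
        n_coarse = n_bins >> level
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        added = False
        for k in ks:
            if n_coarse - k >= 8:
                lag_bins.append(k << level)
                levels.append(level)
                added = True
        if not added or (n_bins >> (level + 1)) < 2 * m:
            break
        level += 1
    return np.asarray(lag_bins, dtype=np.int64), np.asarray(levels, dtype=np.int64)


def _coarsen(x: np.ndarray, level: int) -> np.ndarray:
    for _ in range(level):
        n = (x.size // 2) * 2
        x = 0.5 * (x[0:n:2] + x[1:n:2])
    return x


def _correlate_on_grid(
    counts: np.ndarray, lag_bins: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    g = np.full(lag_bins.size, np.nan)
    coarse = counts
    cur_level = 0
    for i in range(lag_bins.size):
        lvl = int(levels[i])
        while cur_level < lvl:
            coarse = _coarsen(coarse, 1)
            cur_level += 1
        k = int(lag_bins[i]) >> lvl
        if coarse.size - k < 2:
            continue
        x = coarse[: coarse.size - k]
        y = coarse[k:]
        mx = x.mean()
        my = y.mean()
        if mx <= 0 or my <= 0:
            continue
        g[i] = float(np.mean(x * y) / (mx * my) - 1.0)
    return g


def correlate_multi_tau(
    trace: IntensityTrace, m: int = 16, n_segments: int = 0
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a binned intensity trace.

    ``n_segments > 1`` additionally splits the trace into that many equal
    blocks and reports the across-block standard error of G per lag (lags
    not resolvable within a block get NaN stderr).
    """
    counts = np.asarray(trace.counts, dtype=float)
    if counts.size < 2 * m:
        raise ValueError(f"trace must have >= 2m = {2 * m} bins")
    if counts.mean() <= 0:
        raise ValueError("zero-mean trace: normalization undefined")
    lag_bins, levels = multi_tau_lag_grid(counts.size, m)
    g = _correlate_on_grid(counts, lag_bins, levels)
    ok = np.isfinite(g)
    lag_bins, levels, g = lag_bins[ok], levels[ok], g[ok]

    stderr = None
    if n_segments > 1:
        seg_len = counts.size // n_segments
        seg_g = np.full((n_segments, lag_bins.size), np.nan)
        for s in range(n_segments):
            seg = counts[s * seg_len : (s + 1) * seg_len]
            if seg.mean() <= 0:
                continue
            seg_g[s] = _correlate_on_grid(seg, lag_bins, levels)
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            n_ok = np.sum(np.isfinite(seg_g), axis=0)
            stderr = np.where(
                n_ok > 1,
                np.nanstd(seg_g, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1)),
                np.nan,
            )
    return CorrelationCurve(
        lags=lag_bins * trace.bin_time,
        G=g,
        mean_rate=trace.mean_rate,
        stderr=stderr,
        lag_bins=lag_bins,
        levels=levels,
    )
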