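"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the kinetics oracle
integrates the rate equations by explicit Euler stepping (evaluated exactly
via repeated squaring of the one-step matrix), and the correlator oracle
evaluates the multi-tau estimator definition with explicit loops and exact
(fsum) summation.
"""

from __future__ import annotations

import math

import numpy as np


def euler_kinetics_oracle(
    k_blue: float,
    k_bleach_red: float,
    k_bleach_blue: float,
    frames: np.ndarray,
    n_substeps_log2: int = 24,
) -> np.ndarray:
    """Explicit-Euler solution of the red/blue/dark rate equations.

    One frame is divided into 2**n_substeps_log2 Euler steps; the Euler
    iterate over a frame, (I + Q dt)^(2**k), is evaluated by repeated
    squaring (algebraically identical to stepping, without the loop).
    Returns an array (len(frames), 3) of (f_red, f_blue, f_dark).
    """
    q = np.array(
        [
            [-(k_blue + k_bleach_red), 0.0, 0.0],
            [k_blue, -k_bleach_blue, 0.0],
            [k_bleach_red, k_bleach_blue, 0.0],
        ]
    )
    dt = 1.0 / 2**n_substeps_log2
    step = np.eye(3) + q * dt
    for _ in range(n_substeps_log2):
        step = step @ step  # now the per-frame Euler propagator
    out = np.empty((len(frames), 3))
    state = np.array([1.0, 0.0, 0.0])
    frame_of_state = 0
    for i, f in enumerate(frames):
        while frame_of_state < f:
            state = step @ state
            frame_of_state += 1
        out[i] = state
    return out


def direct_multitau_oracle(
    counts: np.ndarray, lag_bins: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """Brute-force evaluation of the multi-tau estimator on its lag grid.

    For each lag the trace is block-averaged to the recorded coarsening
    level, and the symmetric-normalized correlation is accumulated with
    explicit loops and exact summation.
    """
    g = np.empty(len(lag_bins))
    for i, (lag, lvl) in enumerate(zip(lag_bins, levels)):
        c = [float(x) for x in counts]
        for _ in range(int(lvl)):
            n2 = (len(c) // 2) * 2
            c = [(c[j] + c[j + 1]) / 2.0 for j in range(0, n2, 2)]
        k = int(lag) >> int(lvl)
        n = len(c) - k
        sx = math.fsum(c[:n])
        sy = math.fsum(c[k : k + n])
        sxy = math.fsum(c[t] * c[t + k] for t in range(n))
        g[i] = (sxy / n) / ((sx / n) * (sy / n)) - 1.0
    return g


def direct_plain_autocorr(counts: np.ndarray, max_lag: int) -> np.ndarray:
    """Plain symmetric-normalized fluctuation autocorrelation, lags 1..max_lag."""
    c = counts.astype(float)
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        x = c[:-k]
        y = c[k:]
        out[k - 1] = float(np.mean(x * y) / (x.mean() * y.mean()) - 1.0)
    return out
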