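"""Nonlinear least-squares fitting of FCS curves and derived quantities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlate import CorrelationCurve
from .models import FCSModelParams, model_diffusion_2d

__all__ = [
    "FCSFitResult",
    "BeamGeometry",
    "fit_curve",
    "brightness",
    "molecule_percentage",
    "sted_spot_size",
]

ALPHA_BOUNDS = (0.3, 2.0)


@dataclass(frozen=True)
class FCSFitResult:
    """Fitted FCS parameters plus brightness and diagnostics.

    ``fixed_mask`` records which parameters were frozen during the fit.
    ``Q`` is the molecular brightness mean_rate / N (counts s^-1 per
    molecule); NaN when the curve carries no mean rate.
    """

    params: FCSModelParams
    fixed_mask: dict
    Q: float
    reduced_chi2: float
    converged: bool
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class BeamGeometry:
    """Confocal and STED 1/e^2 Gaussian beam radii in nm."""

    omega0_confocal: float
    omega0_sted: float

    def __post_init__(self) -> None:
        if self.omega0_confocal <= 0 or self.omega0_sted <= 0:
            raise ValueError("beam radii must be > 0")
        if self.omega0_sted > self.omega0_confocal:
            warnings.warn(
                "omega0_sted exceeds omega0_confocal; depletion should shrink the spot",
                stacklevel=2,
            )


def _model_g(tau, n, tau_d, alpha, t_frac, tau_trip, use_triplet):
    g = model_diffusion_2d(tau, n, tau_d, alpha)
    if use_triplet:
        g = g * (1.0 - t_frac + t_frac * np.exp(-tau / tau_trip))
    return g


def fit_curve(
    curve: CorrelationCurve,
    use_triplet: bool = False,
    fixed: dict | None = None,
    exclude_first: int = 1,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
    max_lag: float | None = None,
) -> FCSFitResult:
    """Weighted nonlinear least-squares fit of a correlation curve.

    Any parameter (``N``, ``tau_D``, ``alpha``, ``T``, ``tau_triplet``) can
    be frozen through ``fixed``, e.g. ``fixed={"tau_triplet": 5e-6}`` to
    emulate an independently determined triplet time, or
    ``fixed={"alpha": 1.0}`` for free diffusion.  The first correlator bin
    is excluded by default (shot-noise/afterpulsing convention).  Per-lag
    standard errors, when present on the curve, provide the weights.
    Boundary-pinned parameters or failed optimisation are flagged, never
    silent.
    """
    fixed = dict(fixed or {})
    lags = curve.lags[exclude_first:]
    g = curve.G[exclude_first:]
    se = None if curve.stderr is None else curve.stderr[exclude_first:]
    if max_lag is not None:
        keep = lags <= max_lag
        lags, g = lags[keep], g[keep]
        se = None if se is None else se[keep]
    if se is not None:
        # Keep only lags with a usable error estimate; per-lag errors from
        # trace segmentation properly downweight the noisy long-lag tail.
        usable = np.isfinite(se) & (se > 0)
        if usable.sum() >= 6:
            lags, g, se = lags[usable], g[usable], se[usable]
        else:
            se = None
    if lags.size < 6:
        raise ValueError("need >= 6 lag points to fit")

    g0 = float(np.max(g[: max(3, lags.size // 10)]))
    n0 = 1.0 / g0 if g0 > 0 else 1.0
    # tau_D guess: first lag where G drops below half its initial value.
    half = g0 / 2.0
    below = np.nonzero(g < half)[0]
    tau_d0 = float(lags[below[0]]) if below.size else float(lags[lags.size // 2])

    p = lmfit.Parameters()
    p.add("N", value=fixed.get("N", n0), min=1e-8)
    p.add("tau_D", value=fixed.get("tau_D", tau_d0), min=1e-12)
    p.add("alpha", value=fixed.get("alpha", 1.0), min=alpha_bounds[0], max=alpha_bounds[1])
    p.add("T", value=fixed.get("T", 0.1 if use_triplet else 0.0), min=0.0, max=0.95)
    p.add("tau_triplet", value=fixed.get("tau_triplet", 5e-6), min=1e-9)
    for name in ("N", "tau_D", "alpha", "T", "tau_triplet"):
        if name in fixed:
            p[name].set(value=float(fixed[name]), vary=False)
    if not use_triplet:
        p["T"].set(value=0.0, vary=False)
        p["tau_triplet"].set(vary=False)

    weights = 1.0 / se if se is not None else np.ones_like(g)

    def resid(params):
        model = _model_g(
            lags,
            params["N"].value,
            params["tau_D"].value,
            params["alpha"].value,
            params["T"].value,
            params["tau_triplet"].value,
            use_triplet,
        )
        return (model - g) * weights

    res = lmfit.minimize(resid, p, method="leastsq")
    flags: list[str] = []
    if not res.success:
        flags.append(f"non-convergence: {res.message}")
    out = res.params
    for name, (lo, hi) in {
        "alpha": alpha_bounds,
        "T": (0.0, 0.95),
    }.items():
        if out[name].vary:
            v = out[name].value
            if v - lo < 1e-9 * max(abs(lo), 1) and lo not in (0.0,):
                flags.append(f"{name} pinned at lower bound {lo}")
            if hi - v < 1e-9 * max(abs(hi), 1):
                flags.append(f"{name} pinned at upper bound {hi}")
    params = FCSModelParams(
        N=out["N"].value,
        tau_D=out["tau_D"].value,
        alpha=out["alpha"].value,
        T=out["T"].value,
        tau_triplet=out["tau_triplet"].value,
    )
    q = brightness(curve.mean_rate, params.N) if np.isfinite(curve.mean_rate) else float("nan")
    fixed_mask = {name: (not out[name].vary) for name in out}
    return FCSFitResult(
        params=params,
        fixed_mask=fixed_mask,
        Q=q,
        reduced_chi2=float(res.redchi),
        converged=not flags,
        flags=tuple(flags),
    )


def brightness(mean_rate: float, N: float) -> float:
    """Molecular brightness Q = mean count rate / N (counts s^-1 molecule^-1)."""
    if N <= 0:
        raise ValueError("N must be > 0")
    return float(mean_rate) / float(N)


def molecule_percentage(N_t: float, N0_red: float) -> float:
    """Molecule number as a percentage of the initial red-channel N."""
    if N0_red <= 0:
        raise ValueError("initial N must be > 0")
    return 100.0 * float(N_t) / float(N0_red)


def sted_spot_size(tau_D_sted: float, tau_D_conf: float, omega0_conf: float) -> float:
    """Apparent STED spot radius from the transit-time ratio.

    omega0_STED = omega0_confocal * sqrt(tau_D_STED / tau_D_confocal); valid
    because the transit time through a Gaussian spot scales with its area.
    """
    if tau_D_sted <= 0 or tau_D_conf <= 0 or omega0_conf <= 0:
        raise ValueError("all inputs must be > 0")
    return float(omega0_conf) * float(np.sqrt(tau_D_sted / tau_D_conf))
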