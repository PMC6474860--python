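"""Empirical pressure laws fitted to measured geometry series.

Three laws describe how the inflated cornea's geometry tracks pressure:

* shifted power-law thickness  ``T(P) = a - b * P**c``,
* linear radius                ``R(P) = r0 + slope * P``,
* saturating-exponential apex displacement
                               ``D(P) = Dmax * (1 - exp(-P / Pc))``.

The two nonlinear fits are solved by *profiling*: for a fixed value of
the single nonlinear parameter (``c`` or ``Pc``) the remaining parameters
are linear and solved in closed form, and the profiled residual is
minimised by deterministic bounded scalar search.  This avoids random
multistarts, recovers generating parameters on noiseless data to solver
tolerance, and cannot diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateFitError, FitConvergenceError, InvalidParameterError

__all__ = [
    "ThicknessFitParams",
    "RadiusFitParams",
    "DisplacementFitParams",
    "fit_thickness_power",
    "fit_radius_linear",
    "fit_displacement_exponential",
]

# exponent bounds keep b and c identifiable on ~14-point schedules
_C_BOUNDS = (0.05, 1.0)
_PC_BOUNDS = (1e-2, 500.0)


@dataclass(frozen=True)
class ThicknessFitParams:
    a: float  # um
    b: float  # um / mmHg**c
    c: float  # dimensionless
    rss: float
    c_identifiable: bool = True


@dataclass(frozen=True)
class RadiusFitParams:
    intercept: float  # mm
    slope: float  # mm / mmHg
    rss: float


@dataclass(frozen=True)
class DisplacementFitParams:
    Dmax: float  # um
    Pc: float  # mmHg
    rss: float
    Pc_identifiable: bool = True


def _as_arrays(P, y, min_points: int, what: str) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.shape != y.shape or P.ndim != 1:
        raise InvalidParameterError(f"{what}: P and values must be 1-D arrays of equal length")
    if len(P) < min_points:
        raise InvalidParameterError(f"{what}: need at least {min_points} points")
    return P, y


def fit_thickness_power(P, T) -> ThicknessFitParams:
    """Least-squares fit of the shifted power law T = a - b * P**c.

    For fixed exponent c the problem is linear in (a, b); the profiled RSS
    is minimised over c in (0.05, 1) by bounded golden-section/parabolic
    search.  Constant T series return ``b = 0`` with the exponent flagged
    unidentifiable.
    """
    P, T = _as_arrays(P, T, 4, "thickness fit")
    if len(np.unique(P[P > 0])) < 3:
        raise InvalidParameterError("thickness fit needs >= 3 distinct positive pressures")
    if np.ptp(T) < 1e-12 * max(1.0, abs(T[0])):
        return ThicknessFitParams(a=float(T.mean()), b=0.0, c=np.nan, rss=0.0, c_identifiable=False)

    def linear_solve(c: float) -> tuple[float, float, float]:
        X = np.column_stack([np.ones_like(P), -(P**c)])
        coef, _, _, _ = np.linalg.lstsq(X, T, rcond=None)
        resid = T - X @ coef
        return coef[0], coef[1], float(resid @ resid)

    res = minimize_scalar(
        lambda c: linear_solve(c)[2],
        bounds=_C_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    if not res.success:
        raise FitConvergenceError(f"thickness power fit did not converge: {res.message}")
    a, b, rss = linear_solve(float(res.x))
    if a <= 0:
        raise FitConvergenceError("thickness fit produced a non-positive intercept")
    return ThicknessFitParams(a=float(a), b=float(b), c=float(res.x), rss=rss)


def fit_radius_linear(P, R) -> RadiusFitParams:
    """Ordinary least-squares line R = intercept + slope * P."""
    P, R = _as_arrays(P, R, 2, "radius fit")
    if len(np.unique(P)) < 2:
        raise DegenerateFitError("radius fit needs at least 2 distinct pressures")
    X = np.column_stack([np.ones_like(P), P])
    coef, _, _, _ = np.linalg.lstsq(X, R, rcond=None)
    resid = R - X @ coef
    return RadiusFitParams(intercept=float(coef[0]), slope=float(coef[1]), rss=float(resid @ resid))


def fit_displacement_exponential(P, D) -> DisplacementFitParams:
    """Least-squares fit of D = Dmax * (1 - exp(-P / Pc)).

    Dmax is linear given Pc and solved in closed form; the profiled RSS is
    minimised over Pc by deterministic bounded search.  An identically
    zero displacement series returns ``Dmax = 0`` with Pc flagged
    unidentifiable.
    """
    P, D = _as_arrays(P, D, 3, "displacement fit")
    if np.max(np.abs(D)) < 1e-12:
        return DisplacementFitParams(Dmax=0.0, Pc=np.nan, rss=0.0, Pc_identifiable=False)

    def linear_solve(Pc: float) -> tuple[float, float]:
        f = 1.0 - np.exp(-P / Pc)
        denom = f @ f
        if denom == 0:
            return 0.0, float(D @ D)
        dmax = float((D @ f) / denom)
        resid = D - dmax * f
        return dmax, float(resid @ resid)

    res = minimize_scalar(
        lambda pc: linear_solve(pc)[1],
        bounds=_PC_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        raise FitConvergenceError(f"displacement fit did not converge: {res.message}")
    dmax, rss = linear_solve(float(res.x))
    return DisplacementFitParams(Dmax=dmax, Pc=float(res.x), rss=rss)
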