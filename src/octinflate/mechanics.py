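"""Thin-walled-sphere elastic analysis of the inflated cornea.

The cornea is treated as a thin spherical shell clamped at the limbus:
thickness is much smaller than the radius of curvature, so the
circumferential (hoop) stress at pressure P is

    sigma = P * R / (2 * T)            [kPa, with P converted from mmHg]

Deformation is tracked volumetrically through the parabolic fluid cap
under the cornea: the strain is the fractional cap-volume change relative
to the 2 mmHg loading reference,

    epsilon = (V - V_ref) / V_ref

(positive under inflation; the sign convention is chosen so that the
tangent modulus is positive), and the tangent elastic modulus for a
slightly compressible shell (Poisson ratio nu = 0.40) is

    E_c = 3 * (1 - nu) * sigma / epsilon .

Hysteresis is the area enclosed between the loading and unloading
stress-strain curves, integrated on a common strain grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DisjointStrainError,
    InvalidParameterError,
    MissingReferenceError,
)
from .geometry import GeometrySeries, cap_volume

__all__ = [
    "MMHG_TO_KPA",
    "MechanicsConfig",
    "StressStrainCurve",
    "ModulusPoint",
    "HysteresisResult",
    "mmhg_to_kpa",
    "circumferential_stress",
    "volumetric_strain",
    "tangent_modulus",
    "build_curves",
    "hysteresis_area",
]

MMHG_TO_KPA = 0.1333224


@dataclass(frozen=True)
class MechanicsConfig:
    """Material and reference-state configuration.

    ``v`` is Poisson's ratio (slightly compressible tissue), the strain
    reference is the loading state at ``ref_P`` mmHg, and ``cap_base_mm``
    is the clamped cap base width used for cap volumes.
    """

    v: float = 0.40
    mmhg_to_kpa_factor: float = MMHG_TO_KPA
    ref_phase: str = "loading"
    ref_P: float = 2.0
    cap_base_mm: float = 5.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.v < 0.5):
            raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class StressStrainCurve:
    """One phase's (P, sigma, epsilon) points, ordered by pressure."""

    phase: str
    hour: float
    P: np.ndarray
    sigma_kpa: np.ndarray
    epsilon: np.ndarray


@dataclass(frozen=True)
class ModulusPoint:
    P: float
    E_kpa: float
    phase: str
    hour: float = 0.0


@dataclass(frozen=True)
class HysteresisResult:
    area_kpa: float
    area_mmhg: float
    hour: float = 0.0


def mmhg_to_kpa(x: float) -> float:
    """Pressure unit conversion (1 mmHg = 0.1333224 kPa)."""
    return x * MMHG_TO_KPA


def circumferential_stress(P_mmhg: float, R_mm: float, T_um: float) -> float:
    """Hoop stress sigma = P*R/(2*T) of the thin shell, in kPa."""
    if T_um <= 0:
        raise InvalidParameterError("thickness must be positive")
    if R_mm <= 0:
        raise InvalidParameterError("radius must be positive")
    if P_mmhg < 0:
        raise InvalidParameterError("pressure must be non-negative")
    return mmhg_to_kpa(P_mmhg) * R_mm / (2.0 * T_um / 1000.0)


def volumetric_strain(V_ref_mm3: float, V_mm3: float) -> float:
    """Fractional cap-volume change relative to the reference state.

    Positive under inflation (V > V_ref), so the tangent modulus of a
    stiffening shell comes out positive.
    """
    if V_ref_mm3 <= 0:
        raise InvalidParameterError("reference volume must be positive")
    return (V_mm3 - V_ref_mm3) / V_ref_mm3


def tangent_modulus(sigma_kpa: float, epsilon: float, v: float = 0.40) -> float:
    """Tangent elastic modulus E_c = 3*(1 - v)*sigma/epsilon (kPa)."""
    if not (0.0 <= v < 0.5):
        raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")
    if epsilon == 0:
        raise InvalidParameterError("modulus is undefined at the reference state (epsilon = 0)")
    return 3.0 * (1.0 - v) * sigma_kpa / epsilon


def build_curves(
    series: GeometrySeries, cfg: MechanicsConfig | None = None
) -> tuple[list[StressStrainCurve], list[ModulusPoint]]:
    """Stress-strain curves per (hour, phase) plus tangent-modulus points.

    Steps below the reference pressure are excluded (the cornea only
    exhibits its proper curvature from ~2 mmHg).  Strain for *both* phases
    is referenced to the loading state at the reference pressure of the
    same hydration hour; the reference step itself yields no modulus
    point.
    """
    cfg = cfg or MechanicsConfig()
    refs: dict[float, float] = {}
    for r in series:
        if r.phase == cfg.ref_phase and abs(r.P - cfg.ref_P) < 1e-9:
            refs.setdefault(r.hour, cap_volume(r.H_mm, cfg.cap_base_mm))
    curves: list[StressStrainCurve] = []
    moduli: list[ModulusPoint] = []
    hours = sorted({r.hour for r in series})
    for hour in hours:
        if hour not in refs:
            raise MissingReferenceError(
                f"series lacks the {cfg.ref_P} mmHg {cfg.ref_phase} reference at hour {hour}"
            )
        V_ref = refs[hour]
        for phase in ("loading", "unloading"):
            rows = [
                r
                for r in series
                if r.hour == hour and r.phase == phase and r.P >= cfg.ref_P - 1e-9
            ]
            if not rows:
                continue
            rows.sort(key=lambda r: r.P)
            P = np.array([r.P for r in rows])
            sigma = np.array([circumferential_stress(r.P, r.R_mm, r.T_um) for r in rows])
            eps = np.array(
                [volumetric_strain(V_ref, cap_volume(r.H_mm, cfg.cap_base_mm)) for r in rows]
            )
            curves.append(StressStrainCurve(phase, hour, P, sigma, eps))
            for Pi, si, ei in zip(P, sigma, eps):
                if ei != 0:
                    moduli.append(ModulusPoint(float(Pi), tangent_modulus(si, ei, cfg.v), phase, hour))
    return curves, moduli


def hysteresis_area(
    loading: StressStrainCurve, unloading: StressStrainCurve, n_grid: int = 512
) -> HysteresisResult:
    """Area between the loading and unloading stress-strain curves.

    Both curves are linearly interpolated onto a uniform ``n_grid``-point
    strain grid over the intersection of their strain ranges (no
    extrapolation) and the trapezoidal integral of the absolute stress
    difference is taken.  Reported in kPa and, divided by the pressure
    conversion factor, in mmHg.  Symmetric in its two arguments.
    """
    for c in (loading, unloading):
        if len(c.epsilon) < 2:
            raise InvalidParameterError("each curve needs at least 2 points")
    lo = max(loading.epsilon.min(), unloading.epsilon.min())
    hi = min(loading.epsilon.max(), unloading.epsilon.max())
    if hi <= lo:
        raise DisjointStrainError("loading and unloading strain ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)

    def interp(curve: StressStrainCurve) -> np.ndarray:
        order = np.argsort(curve.epsilon, kind="stable")
        return np.interp(grid, curve.epsilon[order], curve.sigma_kpa[order])

    area = float(np.trapezoid(np.abs(interp(loading) - interp(unloading)), grid))
    return HysteresisResult(area_kpa=area, area_mmhg=area / MMHG_TO_KPA, hour=loading.hour)
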