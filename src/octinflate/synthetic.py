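"""Forward model of corneal inflation and synthetic LF-OCT B-scan rendering.

This module is the ground-truth generator for the whole pipeline.  It
emulates an excised cornea clamped at the limbus in an artificial anterior
chamber and inflated hydraulically from 0 to 60 mmHg and back, imaged in
cross-section by a line-field OCT system:

* apex thickness follows a shifted power law of pressure,
  ``T(P) = s(hour) * (a - b * P**c)``, thinning as pressure rises and
  swelling multiplicatively with hydration time;
* the anterior radius of curvature shrinks slightly and linearly,
  ``R(P) = r0 - r1 * P`` (shared between loading and unloading — the two
  phases are experimentally indistinguishable in radius);
* the apex rises toward the instrument with a saturating exponential,
  ``D(P) = Dmax * (1 - exp(-P / Pc))``, fastest below ~20 mmHg;
* unloading states are evaluated at an effective pressure ``P * (1 + lam)``
  for thickness and displacement, which opens the loading/unloading loop
  and is the single dial controlling hysteresis;
* the interior apical (cap) height is bookkept as
  ``H = H2 + dD/1000 + (T2 - T)/1000`` (mm), i.e. the posterior apex rises
  by the anterior rise plus the thinning, with the 2 mmHg loading state as
  reference.

Rendering is geometric: surfaces are reflectivity steps blurred by the
axial point-spread function (Gaussian, FWHM ~3.5 um) with multiplicative
speckle, and the posterior surface is drawn at *optical* depth
``n_group * T`` below the anterior so that downstream refraction
correction is exercised.  No wave-optics is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .errors import CalibrationError, FieldOfViewError, InvalidParameterError
from .segmentation import BScan

__all__ = [
    "PressureStep",
    "PressureSchedule",
    "ForwardModelParams",
    "OpticsConfig",
    "GeometryState",
    "simulate_geometry",
    "swelling_factor",
    "render_bscan",
    "render_stack",
    "dmax_for_peak_displacement",
    "plateau_for_thickness",
    "calibrate_to_modulus",
    "calibrate_hysteresis",
    "replicate_params",
]

#: kPa per mmHg
MMHG_TO_KPA = 0.1333224

# Rendered reflectivity levels (arbitrary units, free choices: the source
# experiments report no image noise/reflectivity model).
_LEVEL_EPITHELIUM = 0.60
_LEVEL_STROMA = 0.35
_LEVEL_AQUEOUS = 0.05
_EPITHELIUM_UM = 100.0  # rendered epithelium band thickness (physical um)


@dataclass(frozen=True)
class PressureStep:
    P: float
    phase: str  # "loading" | "unloading"
    hour: float = 0.0


@dataclass(frozen=True)
class PressureSchedule:
    """Ordered pressure steps driving both simulation and analysis."""

    steps: tuple[PressureStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise InvalidParameterError("schedule must contain at least one step")
        for s in self.steps:
            if s.P < 0:
                raise InvalidParameterError("pressures must be non-negative")
            if s.phase not in ("loading", "unloading"):
                raise InvalidParameterError(f"unknown phase {s.phase!r}")
            if s.hour < 0:
                raise InvalidParameterError("hydration hour must be >= 0")
        # pressures must be monotone within each contiguous same-phase run
        for prev, cur in zip(self.steps, self.steps[1:]):
            if (prev.phase, prev.hour) != (cur.phase, cur.hour):
                continue
            if prev.phase == "loading" and cur.P < prev.P:
                raise InvalidParameterError("loading pressures must be non-decreasing")
            if prev.phase == "unloading" and cur.P > prev.P:
                raise InvalidParameterError("unloading pressures must be non-increasing")

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    @staticmethod
    def default_pressures() -> list[float]:
        """0, 2, then 5 mmHg increments from 5 up to 60."""
        return [0.0, 2.0] + [float(p) for p in range(5, 61, 5)]

    @classmethod
    def loading_only(cls, hour: float = 0.0) -> "PressureSchedule":
        return cls(tuple(PressureStep(p, "loading", hour) for p in cls.default_pressures()))

    @classmethod
    def default_cycle(cls, hour: float = 0.0) -> "PressureSchedule":
        """Full loading phase then its mirror (27 steps, 60 mmHg not repeated)."""
        up = cls.default_pressures()
        down = up[:-1][::-1]
        steps = [PressureStep(p, "loading", hour) for p in up]
        steps += [PressureStep(p, "unloading", hour) for p in down]
        return cls(tuple(steps))

    @classmethod
    def hydration_series(cls, hours: Sequence[float] = (0, 1, 2, 3, 4)) -> "PressureSchedule":
        steps: list[PressureStep] = []
        for h in hours:
            steps.extend(cls.default_cycle(hour=float(h)).steps)
        return cls(tuple(steps))


def _solve_plateau(s1: float, hour: float, s_target: float) -> float:
    """Plateau sinf such that s(1)=s1 and s(hour)=s_target (saturating exp)."""

    def shape(sinf: float) -> float:
        q = (sinf - s1) / (sinf - 1.0)
        return sinf - (sinf - 1.0) * q**hour - s_target

    lo = s_target + 1e-9
    hi = 4.0
    if shape(lo) * shape(hi) > 0:
        raise CalibrationError("cannot bracket swelling plateau for the requested target")
    return float(brentq(shape, lo, hi, xtol=1e-13))


#: Default hour-4 swelling factor: ratio of the 4-hour maximum 0-mmHg
#: thickness to the measured fresh 0-mmHg thickness (1222.47 / 1081).
_DEFAULT_S4 = 1222.47 / 1081.0
_DEFAULT_SINF = _solve_plateau(1.06, 4.0, _DEFAULT_S4)


def dmax_for_peak_displacement(
    delta_um: float = 143.0, Pc: float = 12.0, P_ref: float = 2.0, P_max: float = 60.0
) -> float:
    """Asymptote Dmax such that D(P_max) - D(P_ref) equals ``delta_um``."""
    span = math.exp(-P_ref / Pc) - math.exp(-P_max / Pc)
    if span <= 0:
        raise InvalidParameterError("P_max must exceed P_ref")
    return delta_um / span


_DEFAULT_DMAX = dmax_for_peak_displacement()

#: Default unloading pressure-lag; fixed once by `calibrate_hysteresis`
#: to a fresh-cornea loop area of 0.3 kPa on the noiseless geometry-level
#: pipeline.  The measured fresh-cornea loop (1.4 kPa) is beyond what a
#: quasi-static pressure lag can enclose in this geometry — see
#: docs/methods.md for the bound and the reasoning.
_DEFAULT_LAM = 0.6560228621223256


@dataclass(frozen=True)
class ForwardModelParams:
    """Constitutive and geometric parameters of the simulated cornea.

    Units: ``a`` um, ``b`` um/mmHg^c, ``c`` dimensionless; ``r0`` mm,
    ``r1`` mm/mmHg; ``Dmax`` um, ``Pc`` mmHg; ``lam`` dimensionless;
    ``s1``/``sinf`` dimensionless swelling factors at hour 1 / plateau;
    ``H2`` mm (interior apical height at the 2 mmHg reference); ``B`` mm
    (cap base width, fixed by the chamber).
    """

    a: float = 1085.5
    b: float = 57.3
    c: float = 0.265
    r0: float = 8.448
    r1: float = 0.005
    Dmax: float = _DEFAULT_DMAX
    Pc: float = 12.0
    lam: float = _DEFAULT_LAM
    s1: float = 1.06
    sinf: float = _DEFAULT_SINF
    H2: float = 3.0
    B: float = 5.25

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError("thickness intercept a must be positive")
        if not (0.0 < self.c < 1.0):
            raise InvalidParameterError("thickness exponent c must lie in (0, 1)")
        if self.r0 <= 0:
            raise InvalidParameterError("radius intercept r0 must be positive")
        if self.Dmax < 0:
            raise InvalidParameterError("Dmax must be non-negative")
        if self.Pc <= 0:
            raise InvalidParameterError("Pc must be positive")
        if self.lam < 0:
            raise InvalidParameterError("unloading lag lam must be >= 0")
        if self.s1 < 1.0:
            raise InvalidParameterError("hour-1 swelling factor must be >= 1")
        if self.sinf < self.s1:
            raise InvalidParameterError("swelling plateau must be >= hour-1 factor")
        if self.H2 <= 0 or self.B <= 0:
            raise InvalidParameterError("H2 and B must be positive")


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging-system description for the renderer.

    ``axial_um_per_px`` is micrometres of optical path **in air** per
    pixel; inside tissue the image is stretched by ``n_group``.  The axial
    PSF FWHM must be resolvable (at least one pixel).  ``z_apex_ref_um``
    is the depth of the apex datum: the rendered apex sits at
    ``z_apex_ref_um - D``.
    """

    axial_um_per_px: float = 2.0
    lateral_um_per_px: float = 10.0
    n_rows: int = 1700
    n_cols: int = 800
    n_group: float = 1.389
    psf_fwhm_um: float = 3.5
    speckle_sigma: float = 0.3
    background_level: float = 0.03
    z_apex_ref_um: float = 600.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_group <= 1.0:
            raise InvalidParameterError("group index must exceed 1")
        if self.psf_fwhm_um <= 0:
            raise InvalidParameterError("PSF FWHM must be positive")
        if self.axial_um_per_px > self.psf_fwhm_um:
            raise InvalidParameterError("axial pixel pitch must not exceed the PSF FWHM")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise InvalidParameterError("pixel pitches must be positive")
        if self.speckle_sigma < 0:
            raise InvalidParameterError("speckle scale must be >= 0")

    @property
    def lateral_fov_um(self) -> float:
        return self.n_cols * self.lateral_um_per_px


@dataclass(frozen=True)
class GeometryState:
    """Ground-truth geometry of one schedule step.

    ``T_um`` apex thickness, ``R_mm`` anterior apex radius of curvature,
    ``D_um`` apex axial position relative to the zero-pressure datum
    (positive toward the instrument), ``H_mm`` interior apical height of
    the fluid cap under the cornea.
    """

    P: float
    phase: str
    hour: float
    T_um: float
    R_mm: float
    D_um: float
    H_mm: float


def swelling_factor(hour: float, params: ForwardModelParams | None = None) -> float:
    """Multiplicative hydration swelling of the whole thickness law.

    Saturating exponential ``s(h) = sinf - (sinf - 1) * exp(-rate * h)``
    with ``s(0) = 1`` and the rate fixed by ``s(1) = s1``; monotone
    non-decreasing and bounded by ``sinf``.
    """
    if hour < 0:
        raise InvalidParameterError("hydration hour must be >= 0")
    p = params or ForwardModelParams()
    if p.sinf <= 1.0:
        return 1.0
    q = (p.sinf - p.s1) / (p.sinf - 1.0)  # = exp(-rate)
    return float(p.sinf - (p.sinf - 1.0) * q**hour)


def plateau_for_thickness(
    target_T_um: float, params: ForwardModelParams | None = None, hour: float = 4.0
) -> ForwardModelParams:
    """Params with the swelling plateau set so the zero-pressure thickness
    at ``hour`` equals ``target_T_um`` exactly."""
    p = params or ForwardModelParams()
    s_target = target_T_um / (p.a * 1.0)  # T(0 mmHg) = s * a
    if s_target <= 1.0:
        raise InvalidParameterError("target thickness must exceed the fresh value")
    return replace(p, sinf=_solve_plateau(p.s1, hour, s_target))


def _thickness(P: float, params: ForwardModelParams, swell: float) -> float:
    T = swell * (params.a - params.b * P**params.c)
    if T <= 0:
        raise InvalidParameterError(
            f"thickness law gives non-positive T at P={P} mmHg (extreme parameters)"
        )
    return T


def _displacement(P: float, params: ForwardModelParams) -> float:
    return params.Dmax * (1.0 - math.exp(-P / params.Pc))


def simulate_geometry(
    schedule: PressureSchedule, params: ForwardModelParams | None = None
) -> list[GeometryState]:
    """Evaluate the forward model at every schedule step.

    Loading states follow the constitutive laws directly; unloading states
    evaluate thickness and displacement at the lagged effective pressure
    ``P * (1 + lam)`` (with ``lam = 0`` the loop closes exactly).  The
    radius law is shared between phases.  The cap height is referenced to
    the 2 mmHg loading state of the same hydration hour.
    """
    params = params or ForwardModelParams()
    states: list[GeometryState] = []
    for step in schedule:
        s = swelling_factor(step.hour, params)
        P_eff = step.P * (1.0 + params.lam) if step.phase == "unloading" else step.P
        T = _thickness(P_eff, params, s)
        R = params.r0 - params.r1 * step.P
        if R <= 0:
            raise InvalidParameterError("radius law gives non-positive R")
        D = _displacement(P_eff, params)
        T2 = _thickness(2.0, params, s)
        D2 = _displacement(2.0, params)
        H = params.H2 + (D - D2) / 1000.0 + (T2 - T) / 1000.0
        if H <= 0:
            raise InvalidParameterError("cap height collapsed to zero")
        states.append(GeometryState(step.P, step.phase, step.hour, T, R, D, H))
    return states


# ---------------------------------------------------------------------------
# rendering


def render_bscan(state: GeometryState, optics: OpticsConfig | None = None) -> BScan:
    """Render one synthetic B-scan for a geometry state.

    The anterior surface is a circular arc of radius ``R`` whose apex sits
    at depth ``z_apex_ref_um - D``; the epithelium/stroma interface lies at
    optical depth ``n_group * 100`` um below it and the posterior surface
    at ``n_group * T``.  Interfaces are reflectivity steps blurred by the
    Gaussian axial PSF; multiplicative gamma speckle of the configured
    scale is applied.  Identical (state, optics) pairs render bit-identical
    images.
    """
    optics = optics or OpticsConfig()
    if optics.lateral_fov_um < 6000.0:
        raise FieldOfViewError("lateral field of view must be at least 6 mm")

    x_um = (np.arange(optics.n_cols) - (optics.n_cols - 1) / 2.0) * optics.lateral_um_per_px
    R_um = state.R_mm * 1000.0
    if R_um <= np.abs(x_um).max():
        raise FieldOfViewError("anterior arc narrower than the lateral field")

    z_apex = optics.z_apex_ref_um - state.D_um
    z_ant = z_apex + (R_um - np.sqrt(R_um**2 - x_um**2))
    z_epi = z_ant + optics.n_group * _EPITHELIUM_UM
    z_post = z_ant + optics.n_group * state.T_um

    depth_max = (optics.n_rows - 1) * optics.axial_um_per_px
    margin = 3.0 * optics.psf_fwhm_um
    if z_ant.min() < margin or z_post.max() > depth_max - margin:
        raise FieldOfViewError(
            f"surfaces span {z_ant.min():.0f}-{z_post.max():.0f} um, image covers "
            f"{margin:.0f}-{depth_max - margin:.0f} um"
        )

    z = (np.arange(optics.n_rows) * optics.axial_um_per_px)[:, None]
    sigma = optics.psf_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def step(zc: np.ndarray) -> np.ndarray:
        return 0.5 * (1.0 + erf((z - zc[None, :]) / (sigma * math.sqrt(2.0))))

    levels = optics.background_level
    img = (
        levels
        + (_LEVEL_EPITHELIUM - levels) * step(z_ant)
        + (_LEVEL_STROMA - _LEVEL_EPITHELIUM) * step(z_epi)
        + (_LEVEL_AQUEOUS - _LEVEL_STROMA) * step(z_post)
    )

    if optics.speckle_sigma > 0:
        rng = np.random.default_rng(optics.seed)
        shape = 1.0 / optics.speckle_sigma**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    pixels = np.clip(img * 45000.0, 0, 65535).astype(np.uint16)
    return BScan(
        pixels=pixels,
        axial_um_per_px=optics.axial_um_per_px,
        lateral_um_per_px=optics.lateral_um_per_px,
        n_group=optics.n_group,
    )


def render_stack(
    states: Sequence[GeometryState], optics: OpticsConfig | None = None
) -> list[BScan]:
    """Render one B-scan per state with independent per-step speckle.

    Per-step seeds are spawned deterministically from ``optics.seed`` so a
    stack is reproducible as a whole while steps stay uncorrelated.
    """
    optics = optics or OpticsConfig()
    scans = []
    for i, st in enumerate(states):
        child = int(np.random.SeedSequence([optics.seed, i]).generate_state(1)[0] % (2**31))
        scans.append(render_bscan(st, replace(optics, seed=child)))
    return scans


# ---------------------------------------------------------------------------
# calibration harnesses


def replicate_params(
    base: ForwardModelParams | None = None,
    n: int = 8,
    rel_noise: float = 0.03,
    seed: int = 42,
) -> list[ForwardModelParams]:
    """Simulated replicate eyes: jitter (a, Dmax, s1) multiplicatively.

    Emulates between-eye variability; ``rel_noise`` is the relative
    standard deviation of the jitter.  The swelling jitter is applied to
    the swellable excess ``s1 - 1`` so the hour-0 factor stays exactly 1.
    """
    base = base or ForwardModelParams()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        fa, fd, fs = 1.0 + rel_noise * rng.standard_normal(3)
        s1 = 1.0 + (base.s1 - 1.0) * max(fs, 0.1)
        sinf = 1.0 + (base.sinf - 1.0) * max(fs, 0.1)
        out.append(
            replace(base, a=base.a * fa, Dmax=base.Dmax * max(fd, 0.0), s1=s1, sinf=sinf)
        )
    return out


def _bisect_to_target(
    evaluate: Callable[[float], float],
    x0: float,
    target: float,
    rel_tol: float,
    increasing: bool,
    max_expand: int = 60,
    max_iter: int = 200,
    x_max: float | None = None,
) -> tuple[float, float]:
    """Bisection on a monotone scalar map with geometric bracket expansion.

    ``x_max`` bounds the expansion (used where the map is only monotone on
    a known interval).
    """

    def f(x: float) -> float:
        val = evaluate(x) - target
        return val if increasing else -val

    lo = x0 / 2.0
    hi = min(x0 * 2.0, x_max) if x_max is not None else x0 * 2.0
    flo, fhi = f(lo), f(hi)
    n = 0
    while flo > 0 and n < max_expand:
        hi, fhi = lo, flo
        lo /= 2.0
        flo = f(lo)
        n += 1
    while fhi < 0 and n < max_expand and (x_max is None or hi < x_max):
        lo, flo = hi, fhi
        hi = min(hi * 2.0, x_max) if x_max is not None else hi * 2.0
        fhi = f(hi)
        n += 1
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"target {target} not bracketed; achieved range "
            f"[{min(flo, fhi) + target}, {max(flo, fhi) + target}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        achieved = (fm if increasing else -fm) + target
        if abs(achieved - target) <= rel_tol * abs(target):
            return mid, achieved
        if fm < 0:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection did not reach the requested tolerance")


def calibrate_to_modulus(
    target_E15: float,
    base: ForwardModelParams | None = None,
    pipeline: Callable[[ForwardModelParams], float] | None = None,
    rel_tol: float = 1e-4,
) -> ForwardModelParams:
    """Adjust ``Dmax`` (all else fixed) so the pipeline's loading-phase
    tangent modulus at 15 mmHg hits ``target_E15`` (default tolerance
    0.01 %, comfortably inside the 0.1 % contract).

    ``pipeline`` maps params to E(15 mmHg, loading) in kPa; when omitted a
    noiseless imaging pipeline over a minimal loading schedule is used
    (see `octinflate.pipeline.imaging_modulus_pipeline`).  The modulus is
    monotone decreasing in ``Dmax`` (a softer cornea displaces more per
    unit stress), so bisection with geometric bracket expansion suffices.
    """
    if target_E15 <= 0:
        raise InvalidParameterError("target modulus must be positive")
    base = base or ForwardModelParams()
    if pipeline is None:
        from .pipeline import imaging_modulus_pipeline

        pipeline = imaging_modulus_pipeline(base_params=base)

    def ev(dmax: float) -> float:
        return pipeline(replace(base, Dmax=dmax))

    dmax, _ = _bisect_to_target(ev, base.Dmax, target_E15, rel_tol, increasing=False)
    return replace(base, Dmax=dmax)


def calibrate_hysteresis(
    target_kpa: float,
    base: ForwardModelParams | None = None,
    pipeline: Callable[[ForwardModelParams], float] | None = None,
    rel_tol: float = 1e-4,
) -> ForwardModelParams:
    """Adjust the unloading lag ``lam`` so the loading/unloading loop area
    equals ``target_kpa``.

    Loop area grows monotonically with ``lam`` up to ``lam ~ 3`` (beyond
    that the unloading curve's strain range slides past the loading one
    and the enclosed overlap shrinks again), so bisection is restricted to
    that interval; unreachable targets raise `CalibrationError` with the
    achieved range.  The default pipeline computes the loop on the
    noiseless geometry-level cycle.
    """
    if target_kpa <= 0:
        raise InvalidParameterError("target hysteresis must be positive")
    base = base or ForwardModelParams()
    if pipeline is None:
        from .pipeline import geometry_hysteresis_pipeline

        pipeline = geometry_hysteresis_pipeline()

    def ev(lam: float) -> float:
        return pipeline(replace(base, lam=lam))

    start = base.lam if base.lam > 0 else 0.1
    lam, _ = _bisect_to_target(ev, start, target_kpa, rel_tol, increasing=True, x_max=3.0)
    return replace(base, lam=lam)
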