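"""Geometric measurands from segmented corneal surfaces.

Everything downstream of segmentation reduces to five quantities measured
at the corneal apex: mean thickness over the central 3 mm, anterior radius
of curvature (least-squares circle over the same chord), apex displacement
relative to the 2 mmHg reference, and the height and volume of the
parabolic fluid cap under the cornea (``V = (pi/2) * H * B**2``).
Traces are expected in *physical* micrometres (after refraction
correction) except for the anterior surface, which is physical already.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    InvalidParameterError,
    MissingReferenceError,
    WindowCoverageError,
)
from .segmentation import BScan, DetectionParams, SurfacePair, correct_refraction, detect_surfaces
from .synthetic import GeometryState, PressureSchedule

__all__ = [
    "GeometryRecord",
    "GeometrySeries",
    "apex_thickness",
    "fit_radius",
    "apex_depth",
    "apex_displacement",
    "cap_height",
    "cap_volume",
    "measure_stack",
]

CENTRAL_WINDOW_MM = 3.0


def _fit_circle(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle through (x, z) points.

    Minimises the residual of ``x^2 + z^2 + D x + E z + F = 0``; exact for
    points on a circle and the unique circumcircle for three non-collinear
    points.  Returns (xc, zc, r).
    """
    if len(x) < 3:
        raise DegenerateFitError("need at least 3 points for a circle fit")
    A = np.column_stack([x, z, np.ones_like(x)])
    b = x**2 + z**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateFitError("points are collinear; circle fit is degenerate")
    xc, zc = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + xc**2 + zc**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateFitError("circle fit produced a non-positive radius")
    return float(xc), float(zc), float(np.sqrt(r2))


def _central_window(traces: SurfacePair, window_mm: float) -> np.ndarray:
    """Boolean mask of columns within the central window around the apex.

    The apex column is located at the minimum of the anterior trace; the
    window must be fully covered by the trace.
    """
    half = window_mm * 1000.0 / 2.0
    x = traces.columns_um
    # median of tied minima so a flat anterior centres the window
    near_min = traces.anterior_um <= traces.anterior_um.min() + 1e-9
    apex_x = float(np.median(x[near_min]))
    if apex_x - half < x.min() - 1e-9 or apex_x + half > x.max() + 1e-9:
        raise WindowCoverageError(
            f"central {window_mm} mm window around the apex (at {apex_x:.0f} um) "
            "is not fully covered by the traces"
        )
    return np.abs(x - apex_x) <= half


def apex_thickness(traces: SurfacePair, window_mm: float = CENTRAL_WINDOW_MM) -> float:
    """Mean per-column axial thickness over the central window (um).

    Traces must be in physical units (refraction-corrected).
    """
    mask = _central_window(traces, window_mm)
    return float(np.mean(traces.gap_um[mask]))


def fit_radius(traces: SurfacePair, window_mm: float = CENTRAL_WINDOW_MM) -> float:
    """Anterior radius of curvature (mm) from a least-squares circle over
    the central chord."""
    mask = _central_window(traces, window_mm)
    _, _, r_um = _fit_circle(traces.columns_um[mask], traces.anterior_um[mask])
    return r_um / 1000.0


def apex_depth(traces: SurfacePair, window_mm: float = CENTRAL_WINDOW_MM) -> float:
    """Sub-pixel anterior apex depth (um) as the top of the fitted circle.

    The circle fit pools ~the whole central chord, so the apex depth is far
    less noise-sensitive than the raw per-column minimum.
    """
    mask = _central_window(traces, window_mm)
    _, zc, r_um = _fit_circle(traces.columns_um[mask], traces.anterior_um[mask])
    return float(zc - r_um)


def apex_displacement(current: SurfacePair, reference: SurfacePair) -> float:
    """Apex displacement dD (um), positive when the cornea bulges toward
    the instrument (current apex shallower than the reference apex)."""
    if reference is None:
        raise MissingReferenceError("reference trace (2 mmHg loading) is required")
    return apex_depth(reference) - apex_depth(current)


def cap_height(H2_mm: float, dD_um: float, dT_um: float) -> float:
    """Interior apical cap height H (mm) from the 2 mmHg reference height.

    ``H = H2 + dD/1000 + dT/1000`` with ``dT = T2 - T``: the posterior
    apex rises by the anterior rise plus the thinning.
    """
    if H2_mm <= 0:
        raise InvalidParameterError("reference cap height H2 must be positive")
    H = H2_mm + dD_um / 1000.0 + dT_um / 1000.0
    if H <= 0:
        raise InvalidParameterError("cap height collapsed to a non-positive value")
    return H


def cap_volume(H_mm: float, B_mm: float) -> float:
    """Parabolic cap volume V = (pi/2) * H * B**2 (mm^3)."""
    if H_mm < 0:
        raise InvalidParameterError("cap height must be non-negative")
    if B_mm <= 0:
        raise InvalidParameterError("cap base width must be positive")
    return float(np.pi / 2.0 * H_mm * B_mm**2)


# ---------------------------------------------------------------------------
# series container


@dataclass(frozen=True)
class GeometryRecord:
    P: float
    phase: str
    hour: float
    T_um: float
    R_mm: float
    dD_um: float
    H_mm: float


@dataclass
class GeometrySeries:
    """Ordered per-step geometry, either measured from images or simulated.

    ``provenance`` is ``"measured-from-image"`` or ``"simulated-truth"``.
    ``extra`` carries unknown columns read from CSV so round trips preserve
    them.
    """

    records: list[GeometryRecord]
    provenance: str = "measured-from-image"
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "P_mmHg": [r.P for r in self.records],
                "phase": [r.phase for r in self.records],
                "hour": [r.hour for r in self.records],
                "T_um": [r.T_um for r in self.records],
                "R_mm": [r.R_mm for r in self.records],
                "dD_um": [r.dD_um for r in self.records],
                "H_mm": [r.H_mm for r in self.records],
            }
        )
        df["V_mm3"] = np.nan  # filled by mechanics, which owns the base width
        return df

    @classmethod
    def from_truth(cls, states: Sequence[GeometryState]) -> "GeometrySeries":
        """Convert simulator ground truth to a series (dD referenced to the
        2 mmHg loading state of the same hour)."""
        refs = {
            s.hour: s.D_um
            for s in states
            if s.phase == "loading" and abs(s.P - 2.0) < 1e-9
        }
        records = []
        for s in states:
            if s.hour not in refs:
                raise MissingReferenceError(
                    f"no 2 mmHg loading state at hour {s.hour} to reference dD"
                )
            records.append(
                GeometryRecord(s.P, s.phase, s.hour, s.T_um, s.R_mm, s.D_um - refs[s.hour], s.H_mm)
            )
        return cls(records, provenance="simulated-truth")


def measure_stack(
    scans: Sequence[BScan],
    schedule: PressureSchedule,
    H2_mm: float = 3.0,
    detection: DetectionParams | None = None,
    window_mm: float = CENTRAL_WINDOW_MM,
) -> GeometrySeries:
    """Full geometry extraction for a stack of B-scans.

    Segments every scan, corrects refraction, and measures thickness,
    radius and apex depth; displacement and cap height are referenced to
    the 2 mmHg loading step of the same hydration hour, which must be
    present in the schedule.
    """
    if len(scans) != len(schedule):
        raise InvalidParameterError("one B-scan per schedule step is required")
    measured = []
    for scan, step in zip(scans, schedule):
        traces = correct_refraction(detect_surfaces(scan, detection), scan.n_group)
        measured.append(
            (
                step,
                apex_thickness(traces, window_mm),
                fit_radius(traces, window_mm),
                apex_depth(traces, window_mm),
            )
        )
    refs = {
        step.hour: (T, depth)
        for step, T, _, depth in measured
        if step.phase == "loading" and abs(step.P - 2.0) < 1e-9
    }
    records = []
    for step, T, R, depth in measured:
        if step.hour not in refs:
            raise MissingReferenceError(
                f"schedule lacks the 2 mmHg loading reference at hour {step.hour}"
            )
        T2, depth2 = refs[step.hour]
        dD = depth2 - depth
        records.append(
            GeometryRecord(step.P, step.phase, step.hour, T, R, dD, cap_height(H2_mm, dD, T2 - T))
        )
    return GeometrySeries(records, provenance="measured-from-image")
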