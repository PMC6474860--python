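"""Corneal boundary detection in OCT B-scans and optical-path correction.

A B-scan is a 2-D intensity image whose rows are axial depth (increasing
downward, in micrometres of *optical* path in air) and whose columns are
lateral position.  The cornea appears as two bright interfaces — the
anterior (air/epithelium) and posterior (endothelium/aqueous) surfaces —
with a fainter epithelium/stroma interface in between.  Detection is fully
automated and column-wise: each A-line is searched for axial gradient peaks
above a robust adaptive threshold, the first peak giving the anterior and
the last the posterior boundary.  Traces are then median-filtered and
outlier columns (judged against a local quadratic baseline) are replaced
by interpolation.

Depths below the anterior surface are *optical* path lengths; dividing the
anterior-to-posterior gap by the tissue group refractive index converts
them to physical depth (`correct_refraction`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import savgol_filter

from .errors import (
    InvalidParameterError,
    SegmentationError,
    SurfaceConsistencyError,
)

__all__ = [
    "BScan",
    "DetectionParams",
    "SurfacePair",
    "detect_surfaces",
    "correct_refraction",
]


@dataclass
class BScan:
    """One calibrated cross-sectional OCT image.

    Parameters
    ----------
    pixels
        2-D non-negative intensity array, rows = axial depth, columns =
        lateral position.
    axial_um_per_px
        Axial sampling in micrometres of optical path (in air) per pixel.
    lateral_um_per_px
        Lateral sampling in micrometres per pixel.
    n_group
        Group refractive index of the tissue, used later to convert the
        optical anterior-to-posterior gap to physical thickness.
    """

    pixels: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    n_group: float = 1.389

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 100 or self.pixels.shape[1] < 100:
            raise InvalidParameterError("B-scan must be at least 100 x 100 pixels")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise InvalidParameterError("pixel pitches must be positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DetectionParams:
    """Settings for column-wise gradient-peak boundary detection.

    ``grad_k`` scales the adaptive threshold (column median + k * MAD of
    the axial gradient magnitude).  ``axial_smooth_px``/``lateral_smooth_px``
    control the Gaussian pre-smoothing that suppresses speckle before the
    gradient is taken; speckle is uncorrelated between A-lines while the
    surfaces vary slowly, so lateral smoothing buys noise rejection at no
    cost in boundary localisation.
    """

    grad_k: float = 4.0
    median_width: int = 11
    axial_smooth_px: float = 2.0
    lateral_smooth_px: float = 2.0
    outlier_mad: float = 3.0
    baseline_window: int = 51
    min_detected_frac: float = 0.5
    min_separation_px: int = 10


@dataclass
class SurfacePair:
    """Per-column anterior/posterior boundary depths.

    ``depth_units`` is ``"optical"`` straight out of detection and
    ``"physical"`` after `correct_refraction`.  ``quality`` marks columns
    whose depth was measured directly (``"detected"``) versus filled in by
    interpolation (``"interpolated"``).
    """

    columns_um: np.ndarray
    anterior_um: np.ndarray
    posterior_um: np.ndarray
    quality: np.ndarray
    depth_units: str = "optical"

    def __post_init__(self) -> None:
        n = len(self.columns_um)
        if not (len(self.anterior_um) == len(self.posterior_um) == len(self.quality) == n):
            raise InvalidParameterError("all SurfacePair arrays must share one length")

    @property
    def gap_um(self) -> np.ndarray:
        """Axial anterior-to-posterior separation per column."""
        return self.posterior_um - self.anterior_um


def _first_last_peaks(grad_mag: np.ndarray, threshold: np.ndarray):
    """First and last above-threshold local maxima per column.

    Returns integer row indices (anterior, posterior) and a validity mask.
    Peaks on the first/last row are excluded (no parabolic neighbourhood).
    """
    n_rows = grad_mag.shape[0]
    interior = grad_mag[1:-1]
    is_peak = (
        (interior >= grad_mag[:-2])
        & (interior >= grad_mag[2:])
        & (interior > threshold[None, :])
    )
    any_peak = is_peak.any(axis=0)
    first = is_peak.argmax(axis=0) + 1
    last = n_rows - 2 - is_peak[::-1].argmax(axis=0)
    return first, last, any_peak


def _parabolic_refine(grad_mag: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sub-pixel peak position by 3-point parabola through the gradient peak."""
    y0 = grad_mag[rows - 1, cols]
    y1 = grad_mag[rows, cols]
    y2 = grad_mag[rows + 1, cols]
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    return rows + np.clip(shift, -0.5, 0.5)


def detect_surfaces(image: BScan, params: DetectionParams | None = None) -> SurfacePair:
    """Detect anterior and posterior corneal boundaries in a B-scan.

    Per column the anterior boundary is the first axial local maximum of
    the gradient magnitude above an adaptive threshold (median + k*MAD of
    that column's gradient magnitude) and the posterior boundary is the
    last.  Both traces are median-filtered across columns and columns
    deviating strongly from a local quadratic baseline are replaced by
    interpolation and flagged.

    Returns a `SurfacePair` in **optical** depth micrometres.

    Raises
    ------
    SegmentationError
        If fewer than half of the columns yield a valid boundary pair.
    SurfaceConsistencyError
        If the posterior trace lies at or above the anterior one after
        filtering.
    """
    p = params or DetectionParams()
    img = image.pixels.astype(np.float64)
    img = gaussian_filter(img, sigma=(p.axial_smooth_px, p.lateral_smooth_px), mode="nearest")
    grad_mag = np.abs(np.gradient(img, axis=0))

    med = np.median(grad_mag, axis=0)
    mad = np.median(np.abs(grad_mag - med[None, :]), axis=0)
    threshold = med + p.grad_k * mad

    first, last, valid = _first_last_peaks(grad_mag, threshold)
    valid &= (last - first) >= p.min_separation_px

    frac = float(valid.mean())
    if frac < p.min_detected_frac:
        raise SegmentationError(
            f"boundary pair detected in {frac:.0%} of columns "
            f"(need >= {p.min_detected_frac:.0%})"
        )

    cols = np.arange(image.n_cols)
    ant = np.full(image.n_cols, np.nan)
    post = np.full(image.n_cols, np.nan)
    vc = cols[valid]
    ant[valid] = _parabolic_refine(grad_mag, first[valid], vc)
    post[valid] = _parabolic_refine(grad_mag, last[valid], vc)

    # fill undetected columns, then smooth and reject outliers per surface
    quality_bad = ~valid
    traces = []
    half = p.median_width // 2
    for tr in (ant, post):
        tr = tr.copy()
        tr[~valid] = np.interp(cols[~valid], vc, tr[valid])
        smoothed = median_filter(tr, size=p.median_width, mode="nearest")
        # replicate-padding biases the median on steeply sloped edges of the
        # arc; keep the raw detections there and let the outlier gate act
        smoothed[:half] = tr[:half]
        smoothed[-half:] = tr[-half:]
        tr = smoothed
        window = min(p.baseline_window, len(tr) if len(tr) % 2 == 1 else len(tr) - 1)
        baseline = savgol_filter(tr, window_length=window, polyorder=2, mode="interp")
        resid = tr - baseline
        robust_sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        gate = p.outlier_mad * max(robust_sigma, 0.25)  # floor: quarter pixel
        bad = np.abs(resid) > gate
        if bad.any() and not bad.all():
            # local-quadratic replacement extrapolates cleanly at the edges
            tr[bad] = baseline[bad]
        quality_bad = quality_bad | bad
        traces.append(tr)
    ant, post = traces

    if np.any(post <= ant):
        raise SurfaceConsistencyError("posterior boundary above anterior after filtering")

    scale = image.axial_um_per_px
    quality = np.where(quality_bad, "interpolated", "detected")
    return SurfacePair(
        columns_um=cols * float(image.lateral_um_per_px),
        anterior_um=ant * scale,
        posterior_um=post * scale,
        quality=quality,
        depth_units="optical",
    )


def correct_refraction(traces: SurfacePair, n_group: float) -> SurfacePair:
    """Convert optical depths below the anterior surface to physical depths.

    The anterior trace is unchanged (the beam travels in air above it);
    the anterior-to-posterior optical gap in each column is divided by the
    group refractive index, so physical thickness = optical thickness / n.
    ``n_group = 1`` is the identity.
    """
    if n_group < 1.0:
        raise InvalidParameterError(f"group refractive index must be >= 1, got {n_group}")
    if traces.depth_units != "optical":
        raise InvalidParameterError("traces are already in physical units")
    posterior = traces.anterior_um + traces.gap_um / n_group
    return replace(
        traces,
        posterior_um=posterior,
        anterior_um=traces.anterior_um.copy(),
        columns_um=traces.columns_um.copy(),
        quality=traces.quality.copy(),
        depth_units="physical",
    )
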