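"""File formats: geometry CSV, truth CSV, B-scan stacks, JSON sidecars.

All tables carry their units in the column names; floats are written with
a fixed repr-precision format so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .geometry import GeometryRecord, GeometrySeries
from .segmentation import BScan, SurfacePair
from .synthetic import GeometryState, OpticsConfig, PressureSchedule, PressureStep

__all__ = [
    "read_geometry_csv",
    "write_geometry_csv",
    "read_truth_csv",
    "write_truth_csv",
    "write_surface_csv",
    "read_surface_csv",
    "write_bscan_stack",
    "read_bscan_stack",
    "write_json",
    "file_sha256",
]

FLOAT_FORMAT = "%.10g"

GEOMETRY_COLUMNS = ["P_mmHg", "phase", "hour", "T_um", "R_mm", "dD_um", "H_mm"]
TRUTH_COLUMNS = ["P_mmHg", "phase", "hour", "T_um", "R_mm", "D_um", "H_mm"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def write_geometry_csv(series: GeometrySeries, path) -> None:
    df = series.to_frame()
    if series.extra is not None:
        for col in series.extra.columns:
            df[col] = series.extra[col].values
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_geometry_csv(path) -> GeometrySeries:
    df = pd.read_csv(path)
    _require_columns(df, GEOMETRY_COLUMNS, path)
    records = [
        GeometryRecord(
            float(r.P_mmHg), str(r.phase), float(r.hour),
            float(r.T_um), float(r.R_mm), float(r.dD_um), float(r.H_mm),
        )
        for r in df.itertuples()
    ]
    known = set(GEOMETRY_COLUMNS) | {"V_mm3"}
    extra_cols = [c for c in df.columns if c not in known]
    extra = df[extra_cols].copy() if extra_cols else None
    return GeometrySeries(records, provenance="measured-from-image", extra=extra)


def write_truth_csv(states: Sequence[GeometryState], path) -> None:
    df = pd.DataFrame(
        {
            "P_mmHg": [s.P for s in states],
            "phase": [s.phase for s in states],
            "hour": [s.hour for s in states],
            "T_um": [s.T_um for s in states],
            "R_mm": [s.R_mm for s in states],
            "D_um": [s.D_um for s in states],
            "H_mm": [s.H_mm for s in states],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_truth_csv(path) -> list[GeometryState]:
    df = pd.read_csv(path)
    _require_columns(df, TRUTH_COLUMNS, path)
    return [
        GeometryState(
            float(r.P_mmHg), str(r.phase), float(r.hour),
            float(r.T_um), float(r.R_mm), float(r.D_um), float(r.H_mm),
        )
        for r in df.itertuples()
    ]


def write_surface_csv(pair: SurfacePair, path) -> None:
    pd.DataFrame(
        {
            "column_um": pair.columns_um,
            "anterior_um": pair.anterior_um,
            "posterior_um": pair.posterior_um,
            "quality": pair.quality,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_surface_csv(path, depth_units: str = "optical") -> SurfacePair:
    df = pd.read_csv(path)
    _require_columns(df, ["column_um", "anterior_um", "posterior_um", "quality"], path)
    return SurfacePair(
        columns_um=df["column_um"].to_numpy(float),
        anterior_um=df["anterior_um"].to_numpy(float),
        posterior_um=df["posterior_um"].to_numpy(float),
        quality=df["quality"].to_numpy(str),
        depth_units=depth_units,
    )


def write_bscan_stack(
    scans: Sequence[BScan],
    schedule: PressureSchedule,
    optics: OpticsConfig,
    tiff_path,
    sidecar_path,
) -> None:
    """Multi-page 16-bit grayscale TIFF plus a JSON calibration sidecar."""
    stack = np.stack([s.pixels for s in scans])
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    sidecar = {
        "axial_um_per_px": optics.axial_um_per_px,
        "lateral_um_per_px": optics.lateral_um_per_px,
        "n_group": optics.n_group,
        "psf_fwhm_um": optics.psf_fwhm_um,
        "speckle_sigma": optics.speckle_sigma,
        "seed": optics.seed,
        "schedule": [
            {"P_mmHg": st.P, "phase": st.phase, "hour": st.hour} for st in schedule
        ],
    }
    write_json(sidecar, sidecar_path)


def read_bscan_stack(tiff_path, sidecar_path) -> tuple[list[BScan], PressureSchedule]:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    scans = [
        BScan(
            pixels=page,
            axial_um_per_px=meta["axial_um_per_px"],
            lateral_um_per_px=meta["lateral_um_per_px"],
            n_group=meta["n_group"],
        )
        for page in stack
    ]
    schedule = PressureSchedule(
        tuple(PressureStep(s["P_mmHg"], s["phase"], s["hour"]) for s in meta["schedule"])
    )
    return scans, schedule


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
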