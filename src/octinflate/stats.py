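"""Hydration-effect summaries and exact small-sample significance tests.

The source experiments compare n = 8 paired eyes across hydration hours,
where the normal approximation to the Wilcoxon signed-rank null is poor;
the test here enumerates all 2**n equiprobable sign assignments of the
(mid)ranked absolute differences and reports the exact two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidParameterError, MissingReferenceError, UndefinedTestError

__all__ = [
    "EyeMechanics",
    "HydrationSummary",
    "percent_change",
    "wilcoxon_signed_rank_exact",
    "hydration_summary",
]


def percent_change(x0: float, x1: float) -> float:
    """Percent change 100 * (x1 - x0) / x0 of a quantity from its baseline."""
    if x0 == 0:
        raise InvalidParameterError("percent change is undefined for a zero baseline")
    return 100.0 * (x1 - x0) / x0


def wilcoxon_signed_rank_exact(diffs: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value by full enumeration.

    Zero differences are dropped (standard convention); ties in the
    absolute differences receive midranks.  The null distribution of the
    positive-rank sum W+ is built by enumerating all 2**n sign vectors
    (n <= 20), and the two-sided p is twice the smaller tail probability,
    capped at 1.  No normal approximation is involved, so the p-value
    granularity matches small-sample tables exactly (e.g. n = 8, all
    positive: p = 2/256 = 0.0078125).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero; test undefined")
    if n > 20:
        raise InvalidParameterError("exact enumeration supported for n <= 20 only")
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    # all 2**n values of W+ by iterative doubling
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    p_low = float(np.mean(sums <= w_obs + eps))
    p_high = float(np.mean(sums >= w_obs - eps))
    return min(1.0, 2.0 * min(p_low, p_high))


@dataclass(frozen=True)
class EyeMechanics:
    """Per-eye, per-hour scalar mechanics outputs feeding the summary."""

    hour: float
    thickness0_um: float  # apex thickness at 0 mmHg
    E15_kpa: float  # loading-phase tangent modulus at 15 mmHg
    hysteresis_kpa: float
    hysteresis_mmhg: float


@dataclass
class HydrationSummary:
    """Per-hour means, percent changes vs hour 0, and exact p-values."""

    table: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def hydration_summary(results: Sequence[EyeMechanics]) -> HydrationSummary:
    """Aggregate replicate-eye mechanics across hydration hours.

    For each hour the mean 0-mmHg thickness, 15-mmHg loading modulus and
    hysteresis are tabulated together with their percent change versus
    hour 0 and the exact Wilcoxon signed-rank p-value of the paired
    hour-vs-hour-0 comparison across eyes.  Requires hour 0 plus at least
    one later hour, with the same number of eyes per hour.
    """
    if not results:
        raise InvalidParameterError("no mechanics results supplied")
    by_hour: dict[float, list[EyeMechanics]] = {}
    for r in results:
        by_hour.setdefault(r.hour, []).append(r)
    hours = sorted(by_hour)
    if 0.0 not in by_hour:
        raise MissingReferenceError("hydration summary requires hour-0 results")
    if len(hours) < 2:
        raise InvalidParameterError("hydration summary requires at least 2 hours")
    n0 = len(by_hour[0.0])
    for h in hours:
        if len(by_hour[h]) != n0:
            raise InvalidParameterError("each hour must have the same number of eyes")

    def column(h: float, attr: str) -> np.ndarray:
        return np.array([getattr(e, attr) for e in by_hour[h]])

    rows = []
    for h in hours:
        row: dict[str, float] = {"hour": h}
        for attr, name in [
            ("thickness0_um", "thickness0_um"),
            ("E15_kpa", "E15_kpa"),
            ("hysteresis_kpa", "hysteresis_kpa"),
            ("hysteresis_mmhg", "hysteresis_mmhg"),
        ]:
            vals = column(h, attr)
            base = column(0.0, attr)
            row[name] = float(vals.mean())
            row[f"{name}_pct_change"] = (
                0.0 if h == 0.0 else percent_change(float(base.mean()), float(vals.mean()))
            )
        for attr in ("thickness0_um", "E15_kpa", "hysteresis_kpa"):
            if h == 0.0:
                row[f"{attr}_p"] = np.nan
            else:
                diffs = column(h, attr) - column(0.0, attr)
                try:
                    row[f"{attr}_p"] = wilcoxon_signed_rank_exact(diffs)
                except UndefinedTestError:
                    row[f"{attr}_p"] = np.nan
        rows.append(row)
    return HydrationSummary(table=pd.DataFrame(rows))
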