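"""Glycemic-range (IR/AR/BR) and day/night labelling of retained windows.

The glycemic ranges follow the Time-in-Tight-Range convention: in range (IR)
for glucose in 70-140 mg/dL inclusive, above range (AR) strictly above 140,
below range (BR) strictly below 70. Daytime is the half-open wall-clock
interval [06:00, 21:00); nighttime is its complement — each boundary instant
belongs to the period it opens.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

TIGHT_RANGE_MG_DL = (70.0, 140.0)
DAYTIME_HOURS = (6, 21)


class GlycemicLabel(str, Enum):
    IR = "IR"
    AR = "AR"
    BR = "BR"


class PeriodLabel(str, Enum):
    DAYTIME = "daytime"
    NIGHTTIME = "nighttime"


def classify_glycemia(
    glucose: float, tight_range: tuple[float, float] = TIGHT_RANGE_MG_DL
) -> GlycemicLabel:
    """BR below the tight range, AR above it, IR otherwise (bounds inclusive)."""
    if not glucose > 0:
        raise ValueError(f"non-positive glucose {glucose!r}")
    lo, hi = tight_range
    if glucose < lo:
        return GlycemicLabel.BR
    if glucose > hi:
        return GlycemicLabel.AR
    return GlycemicLabel.IR


def classify_period(
    timestamp: pd.Timestamp, daytime_hours: tuple[int, int] = DAYTIME_HOURS
) -> PeriodLabel:
    """Daytime iff 06:00 <= wall clock < 21:00 (default hours)."""
    start, end = daytime_hours
    seconds = timestamp.hour * 3600 + timestamp.minute * 60 + timestamp.second
    return PeriodLabel.DAYTIME if start * 3600 <= seconds < end * 3600 else PeriodLabel.NIGHTTIME


def stratify(
    series: pd.DataFrame,
    tight_range: tuple[float, float] = TIGHT_RANGE_MG_DL,
    daytime_hours: tuple[int, int] = DAYTIME_HOURS,
) -> pd.DataFrame:
    """Append ``glycemic_label`` and ``period`` columns to a metric series.

    Vectorized but exactly equivalent to applying :func:`classify_glycemia`
    and :func:`classify_period` row-wise.
    """
    out = series.copy()
    if len(out) == 0:
        out["glycemic_label"] = pd.Series(dtype=object)
        out["period"] = pd.Series(dtype=object)
        return out
    g = out["glucose"].to_numpy(dtype=float)
    if not (g > 0).all():
        raise ValueError("non-positive glucose in stratification input")
    lo, hi = tight_range
    label = np.where(g < lo, GlycemicLabel.BR.value,
                     np.where(g > hi, GlycemicLabel.AR.value, GlycemicLabel.IR.value))
    ts = pd.DatetimeIndex(out["cgm_timestamp"])
    secs = ts.hour * 3600 + ts.minute * 60 + ts.second
    start, end = daytime_hours
    day = (secs >= start * 3600) & (secs < end * 3600)
    out["glycemic_label"] = label
    out["period"] = np.where(day, PeriodLabel.DAYTIME.value, PeriodLabel.NIGHTTIME.value)
    return out


def cell_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Window counts per (glycemic label, period) cell; sums to total rows."""
    if len(labeled) == 0:
        return pd.DataFrame(columns=["glycemic_label", "period", "n_windows"])
    counts = (
        labeled.groupby(["glycemic_label", "period"], observed=True)
        .size()
        .rename("n_windows")
        .reset_index()
    )
    return counts
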