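"""Readers and validators for per-subject CGM / skin-temperature CSV pairs.

Each subject folder holds two two-column CSV files with a single header row:

* ``Dexcom.csv`` — timestamp, interstitial glucose in mg/dL (one sample / 5 min)
* ``TEMP.csv``   — timestamp, wrist skin temperature in °C (4 Hz)

Timestamps are parsed timezone-naive and interpreted as local clock time,
because downstream day/night stratification works on wall-clock hours.
Non-numeric or empty value cells become NaN (a missing sample at that
timestamp), never silently dropped rows; duplicate timestamps keep the first
occurrence and log the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CGM_FILENAME = "Dexcom.csv"
TEMP_FILENAME = "TEMP.csv"

#: nominal CGM cadence, seconds
CGM_PERIOD_S = 300
#: nominal skin-temperature sampling rate, Hz
TEMP_HZ = 4


@dataclass
class Trace:
    """An ordered, timestamped sample stream for one subject.

    ``values`` may contain NaN, meaning the device reported a row at that
    timestamp but the value is missing; absent timestamps are simply not in
    ``times``.
    """

    subject_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""
    n_malformed_rows: int = 0
    n_duplicate_timestamps: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("trace timestamps must be sorted")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> pd.Timedelta:
        """First-to-last timestamp duration (zero for <2 samples)."""
        if len(self) < 2:
            return pd.Timedelta(0)
        return self.times[-1] - self.times[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "value": self.values})


@dataclass
class CGMTrace(Trace):
    units: str = "mg/dL"


@dataclass
class TemperatureTrace(Trace):
    units: str = "degC"


@dataclass
class CompletenessSummary:
    """CGM completeness over the subject's own observed monitoring span."""

    subject_id: str
    expected_cgm_samples: int
    observed_cgm_samples: int
    percent_missing_cgm: float
    monitoring_span: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(0))


def _read_two_column_csv(
    path: str | Path, subject_id: str | None
) -> tuple[str, pd.DatetimeIndex, np.ndarray, int, int]:
    path = Path(path)
    if subject_id is None:
        subject_id = path.parent.name or path.stem
    frame = pd.read_csv(path, header=0, usecols=[0, 1], float_precision="round_trip")
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected a two-column CSV")
    ts = pd.to_datetime(frame.iloc[:, 0], errors="coerce", format="mixed")
    vals = pd.to_numeric(frame.iloc[:, 1], errors="coerce")

    bad_ts = ts.isna()
    n_malformed = int(bad_ts.sum())
    if n_malformed:
        logger.warning("%s: %d rows with unparseable timestamps dropped", path, n_malformed)
    ts, vals = ts[~bad_ts], vals[~bad_ts]

    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = pd.DatetimeIndex(ts.to_numpy()[order])
    vals = vals.to_numpy()[order]

    dup = np.asarray(ts.duplicated(keep="first"))
    n_dup = int(dup.sum())
    if n_dup:
        logger.warning("%s: %d duplicate timestamps, keeping first occurrence", path, n_dup)
        ts, vals = ts[~dup], vals[~dup]

    if len(ts) == 0:
        logger.warning("%s: empty data section", path)
    return subject_id, ts, np.asarray(vals, dtype=float), n_malformed, n_dup


def read_cgm_csv(path: str | Path, subject_id: str | None = None) -> CGMTrace:
    """Read a Dexcom-style CSV into a :class:`CGMTrace`, sorted by time."""
    sid, ts, vals, n_bad, n_dup = _read_two_column_csv(path, subject_id)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite <= 0).any():
        raise ValueError(f"{path}: non-positive glucose values")
    return CGMTrace(sid, ts, vals, n_malformed_rows=n_bad, n_duplicate_timestamps=n_dup)


def read_temperature_csv(path: str | Path, subject_id: str | None = None) -> TemperatureTrace:
    """Read a TEMP-style CSV into a :class:`TemperatureTrace`, sorted by time.

    No physiological screening happens here — a 27.5 °C value parses as
    27.5 °C; the artifact rule is applied later, per window.
    """
    sid, ts, vals, n_bad, n_dup = _read_two_column_csv(path, subject_id)
    return TemperatureTrace(sid, ts, vals, n_malformed_rows=n_bad, n_duplicate_timestamps=n_dup)


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace back to the two-column CSV dialect (round-trip exact)."""
    frame = trace.to_frame()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.%f")
    frame.to_csv(path, index=False)


def summarize_completeness(cgm: CGMTrace, period_s: int = CGM_PERIOD_S) -> CompletenessSummary:
    """CGM missingness on the subject's own first-to-last-timestamp span.

    ``expected = floor(span / period) + 1``; a sample with a NaN glucose value
    counts as missing even though its timestamp is present.
    """
    if len(cgm) == 0:
        raise ValueError(f"subject {cgm.subject_id}: empty CGM trace, unusable")
    span = cgm.span
    expected = int(span.total_seconds() // period_s) + 1
    observed = int(np.isfinite(cgm.values).sum())
    observed = min(observed, expected)
    pct_missing = 100.0 * (1.0 - observed / expected)
    return CompletenessSummary(
        subject_id=cgm.subject_id,
        expected_cgm_samples=expected,
        observed_cgm_samples=observed,
        percent_missing_cgm=pct_missing,
        monitoring_span=span,
    )


def read_subject_folder(folder: str | Path) -> tuple[CGMTrace, TemperatureTrace]:
    """Read the ``Dexcom.csv`` / ``TEMP.csv`` pair of one subject folder."""
    folder = Path(folder)
    sid = folder.name
    return (
        read_cgm_csv(folder / CGM_FILENAME, subject_id=sid),
        read_temperature_csv(folder / TEMP_FILENAME, subject_id=sid),
    )
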