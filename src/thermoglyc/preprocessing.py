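"""Subject exclusion, backward 5-min window alignment, and window screening.

The temperature stream is cut into windows aligned *backward* to each CGM
timestamp ``t``: a window covers the half-open interval ``(t - 300 s, t]`` and
must contain exactly N = 5 * 60 * 4 = 1200 samples to be usable. Each candidate
window then gets exactly one verdict, with deterministic precedence:

1. ``missing_glucose``     — the CGM value at ``t`` is absent
2. ``missing_temperature`` — fewer than N samples fall in the interval
3. ``artifact``            — any sample strictly below the 28 °C floor
4. ``outlier``             — any sample strictly outside mean ± 5 SD
   (window-local mean and sample SD)
5. ``retained``

Equality at a screening bound (exactly 28.000 °C, exactly at mean ± 5 SD)
retains the sample; a constant window has SD = 0 and passes the outlier rule.
No imputation or resampling is performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .data_io import CGMTrace, CompletenessSummary, TemperatureTrace

logger = logging.getLogger(__name__)


class Verdict(str, Enum):
    RETAINED = "retained"
    MISSING_GLUCOSE = "discarded_missing_glucose"
    MISSING_TEMPERATURE = "discarded_missing_temperature"
    ARTIFACT = "discarded_artifact"
    OUTLIER = "discarded_outlier"


DISCARD_VERDICTS = [
    Verdict.MISSING_GLUCOSE,
    Verdict.MISSING_TEMPERATURE,
    Verdict.ARTIFACT,
    Verdict.OUTLIER,
]


@dataclass
class PreprocessConfig:
    """Screening thresholds; defaults follow the analysis they implement."""

    artifact_floor_c: float = 28.0
    outlier_sd_multiplier: float = 5.0
    cgm_missing_exclusion_pct: float = 20.0
    window_seconds: int = 300
    temp_hz: int = 4

    @property
    def samples_per_window(self) -> int:
        return self.window_seconds * self.temp_hz

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class AlignedWindow:
    """One 5-min temperature block tied to one CGM sample."""

    index_i: int  # 1-based chronological ordinal within subject
    cgm_timestamp: pd.Timestamp
    glucose: float
    samples: np.ndarray  # empty when the interval was under-filled
    verdict: Verdict


@dataclass
class WindowSet:
    """All candidate windows of one subject, column-wise.

    ``samples`` has one row per candidate window; rows for under-filled or
    glucose-missing windows are NaN-padded and never consulted downstream.
    """

    subject_id: str
    cgm_timestamps: pd.DatetimeIndex
    glucose: np.ndarray
    samples: np.ndarray  # (n_windows, N)
    verdicts: np.ndarray  # of Verdict .value strings

    def __len__(self) -> int:
        return len(self.cgm_timestamps)

    @property
    def retained_mask(self) -> np.ndarray:
        return self.verdicts == Verdict.RETAINED.value

    def retained(self) -> "WindowSet":
        m = self.retained_mask
        return WindowSet(
            self.subject_id,
            self.cgm_timestamps[m],
            self.glucose[m],
            self.samples[m],
            self.verdicts[m],
        )

    def windows(self) -> list[AlignedWindow]:
        """Materialize per-window objects (1-based chronological indices)."""
        return [
            AlignedWindow(i + 1, self.cgm_timestamps[i], self.glucose[i],
                          self.samples[i], Verdict(self.verdicts[i]))
            for i in range(len(self))
        ]


@dataclass
class PreprocessReport:
    subject_id: str
    windows_total: int
    windows_retained: int
    discard_counts: dict = field(default_factory=dict)

    @property
    def percent_retained(self) -> float:
        if self.windows_total == 0:
            return float("nan")
        return 100.0 * self.windows_retained / self.windows_total

    def check_conservation(self) -> bool:
        return self.windows_retained + sum(self.discard_counts.values()) == self.windows_total

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "windows_total": self.windows_total,
            "windows_retained": self.windows_retained,
            "percent_retained": self.percent_retained,
        }
        row.update({v.value: self.discard_counts.get(v, 0) for v in DISCARD_VERDICTS})
        return row


def exclude_subject(summary: CompletenessSummary, threshold_pct: float = 20.0) -> bool:
    """True = exclude. Strictly-greater rule: exactly at threshold is kept."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    return summary.percent_missing_cgm > threshold_pct


def align_windows(
    temp: TemperatureTrace, cgm: CGMTrace, config: PreprocessConfig | None = None
) -> WindowSet:
    """One candidate window per CGM timestamp, backward over ``(t-300 s, t]``.

    Windows whose glucose is NaN are marked ``missing_glucose``; windows whose
    interval holds != N temperature samples are ``missing_temperature``.
    Screening for artifacts/outliers happens separately.
    """
    config = config or PreprocessConfig()
    n_win = len(cgm)
    n_samp = config.samples_per_window
    t = cgm.times.asi8  # ns
    window_ns = config.window_seconds * 1_000_000_000
    tt = temp.times.asi8
    right = np.searchsorted(tt, t, side="right")
    left = np.searchsorted(tt, t - window_ns, side="right")
    counts = right - left

    verdicts = np.empty(n_win, dtype=object)
    verdicts[:] = Verdict.RETAINED.value
    verdicts[counts != n_samp] = Verdict.MISSING_TEMPERATURE.value
    # windows with the right count but any NaN sample are also under-filled
    samples = np.full((n_win, n_samp), np.nan)
    full = counts == n_samp
    if full.any():
        idx = left[full][:, None] + np.arange(n_samp)[None, :]
        block = temp.values[idx]
        nan_rows = ~np.isfinite(block).all(axis=1)
        samples[full] = block
        if nan_rows.any():
            sub = np.flatnonzero(full)[nan_rows]
            verdicts[sub] = Verdict.MISSING_TEMPERATURE.value
    # glucose-missing takes precedence over everything
    verdicts[~np.isfinite(cgm.values)] = Verdict.MISSING_GLUCOSE.value
    return WindowSet(cgm.subject_id, cgm.times, np.asarray(cgm.values, float), samples, verdicts)


def _screen_mask(samples: np.ndarray, floor: float, k: float) -> tuple[np.ndarray, np.ndarray]:
    """(artifact, outlier) boolean masks for rows of a (n, N) sample block."""
    artifact = (samples < floor).any(axis=1)
    mean = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    outside = (samples < mean - k * sd) | (samples > mean + k * sd)
    return artifact, outside.any(axis=1)


def screen_window(w: AlignedWindow, config: PreprocessConfig | None = None) -> AlignedWindow:
    """Final verdict for one fully-sampled candidate window."""
    config = config or PreprocessConfig()
    if w.verdict in (Verdict.MISSING_GLUCOSE, Verdict.MISSING_TEMPERATURE):
        return w
    s = np.asarray(w.samples, float)[None, :]
    artifact, outlier = _screen_mask(s, config.artifact_floor_c, config.outlier_sd_multiplier)
    verdict = Verdict.ARTIFACT if artifact[0] else (Verdict.OUTLIER if outlier[0] else Verdict.RETAINED)
    return AlignedWindow(w.index_i, w.cgm_timestamp, w.glucose, w.samples, verdict)


def screen_windows(ws: WindowSet, config: PreprocessConfig | None = None) -> WindowSet:
    """Vectorized screening of every still-candidate window in a set."""
    config = config or PreprocessConfig()
    cand = ws.verdicts == Verdict.RETAINED.value
    if cand.any():
        artifact, outlier = _screen_mask(
            ws.samples[cand], config.artifact_floor_c, config.outlier_sd_multiplier
        )
        idx = np.flatnonzero(cand)
        ws.verdicts[idx[artifact]] = Verdict.ARTIFACT.value
        ws.verdicts[idx[~artifact & outlier]] = Verdict.OUTLIER.value
    return ws


def preprocess_subject(
    temp: TemperatureTrace, cgm: CGMTrace, config: PreprocessConfig | None = None
) -> tuple[WindowSet, PreprocessReport]:
    """Align then screen; returns the retained windows and a conserving report."""
    config = config or PreprocessConfig()
    ws = screen_windows(align_windows(temp, cgm, config), config)
    counts = {v: int((ws.verdicts == v.value).sum()) for v in DISCARD_VERDICTS}
    report = PreprocessReport(
        subject_id=cgm.subject_id,
        windows_total=len(ws),
        windows_retained=int(ws.retained_mask.sum()),
        discard_counts=counts,
    )
    assert report.check_conservation()
    logger.info(
        "subject %s: %d/%d windows retained (%.1f%%), discards %s",
        report.subject_id, report.windows_retained, report.windows_total,
        report.percent_retained, {v.value: c for v, c in counts.items()},
    )
    return ws.retained(), report
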