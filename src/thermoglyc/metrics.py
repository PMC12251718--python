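"""Current-behavior and retrospective skin-temperature variability metrics.

For the i-th retained window with samples ``st_i1 .. st_iN`` (°C):

Current-behavior (window-local) metrics
    mean_T, median_T, SD_T (sample SD, N-1 denominator), IQR_T (linear
    interpolation between order statistics), CV_T = SD_T / mean_T, and

    * ``MAD_T = 1.4826 * mean_k |st_ik - median_T|`` — mean amplitude
      deviation; 1.4826 gives asymptotically normal consistency.
    * ``J_T = 0.001 * (mean_T + SD_T)^2`` — J-index adapted from the
      glycemic domain: joint level + variability score.
    * ``M1_T, M2_T = mean_k |10 * log10(st_ik / r)|^3`` — M-value adapted
      from the glycemic domain, the mean cubed absolute log10-deviation from
      a reference temperature r (r1 = 36 °C maximal, r2 = 32 °C mean level).

Retrospective metrics at window i use windows 1..i (retained only, whole
recording, day and night interleaved), in the population (divide-by-i) form:

    * ``CV_T_mean = mean(CV_T_1 .. CV_T_i)``
    * ``CV_T_SD   = sqrt( sum_k (CV_T_k - CV_T_mean)^2 / i )``
    * ``SD_T_hhmm = sqrt( sum_k (mean_T_k - m)^2 / i )`` with m the grand
      mean of every sample in windows 1..i; with all windows the same length
      N, m equals the mean of the window means (asserted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import WindowSet

#: reference temperatures (°C) for the M-value adaptations
R1_MAX_C = 36.0
R2_MEAN_C = 32.0

CURRENT_METRIC_NAMES = [
    "mean_T", "median_T", "SD_T", "IQR_T", "CV_T", "MAD_T", "J_T", "M1_T", "M2_T",
]
RETRO_METRIC_NAMES = ["CV_T_mean", "CV_T_SD", "SD_T_hhmm"]
ALL_METRIC_NAMES = CURRENT_METRIC_NAMES + RETRO_METRIC_NAMES


@dataclass
class CurrentMetrics:
    mean_T: float
    median_T: float
    SD_T: float
    IQR_T: float
    CV_T: float
    MAD_T: float
    J_T: float
    M1_T: float
    M2_T: float


@dataclass
class RetrospectiveMetrics:
    CV_T_mean: float
    CV_T_SD: float
    SD_T_hhmm: float


def _m_value(log10_block: np.ndarray, r: float, literal_cube_inside_log: bool) -> np.ndarray:
    dev = np.abs(10.0 * (log10_block - np.log10(r)))
    if literal_cube_inside_log:
        # 10*|log10((st/r)^3)| = 30*|log10(st/r)|
        return (3.0 * dev).mean(axis=1)
    return (dev * dev * dev).mean(axis=1)


def current_metrics_block(
    samples: np.ndarray,
    r1: float = R1_MAX_C,
    r2: float = R2_MEAN_C,
    literal_cube_inside_log: bool = False,
) -> pd.DataFrame:
    """Current-behavior metrics for a (n_windows, N) block, one row per window."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if not np.isfinite(samples).all():
        raise ValueError("non-finite temperature sample reached metric computation")
    if (samples <= 0).any():
        raise ValueError("non-positive temperature (log-deviation undefined)")
    mean = samples.mean(axis=1)
    q25, median, q75 = np.percentile(samples, [25, 50, 75], axis=1)
    sd = samples.std(axis=1, ddof=1) if samples.shape[1] > 1 else np.zeros(len(samples))
    log10_s = np.log10(samples)
    return pd.DataFrame({
        "mean_T": mean,
        "median_T": median,
        "SD_T": sd,
        "IQR_T": q75 - q25,
        "CV_T": sd / mean,
        "MAD_T": 1.4826 * np.abs(samples - median[:, None]).mean(axis=1),
        "J_T": 0.001 * (mean + sd) ** 2,
        "M1_T": _m_value(log10_s, r1, literal_cube_inside_log),
        "M2_T": _m_value(log10_s, r2, literal_cube_inside_log),
    })


def current_metrics(
    samples: np.ndarray, r1: float = R1_MAX_C, r2: float = R2_MEAN_C, **kw
) -> CurrentMetrics:
    """Current-behavior metrics for a single window (1-D sample vector)."""
    row = current_metrics_block(np.asarray(samples)[None, :], r1, r2, **kw).iloc[0]
    return CurrentMetrics(**row.to_dict())


def retrospective_cv(cv_history: np.ndarray) -> tuple[float, float]:
    """Running mean and population SD of the CV series over windows 1..i."""
    cv = np.asarray(cv_history, dtype=float)
    if cv.size == 0:
        raise ValueError("empty CV history")
    m = cv.mean()
    return float(m), float(np.sqrt(((cv - m) ** 2).mean()))


def sd_hhmm(window_means: np.ndarray, grand_mean: float | None = None) -> float:
    """Population SD of window means about the grand sample mean m.

    With equal-length windows m is the mean of the window means, which is the
    default when ``grand_mean`` is not given.
    """
    wm = np.asarray(window_means, dtype=float)
    if wm.size == 0:
        raise ValueError("empty window-mean history")
    m = wm.mean() if grand_mean is None else grand_mean
    return float(np.sqrt(((wm - m) ** 2).mean()))


def retrospective_metrics_series(current: pd.DataFrame) -> pd.DataFrame:
    """Retrospective metrics at every window, via running sums.

    Equivalent (to ~1e-12 relative) to recomputing Eq.-style from scratch at
    each i; running sums keep the whole series O(n).
    """
    cv = current["CV_T"].to_numpy()
    wm = current["mean_T"].to_numpy()
    i = np.arange(1, len(cv) + 1, dtype=float)
    cv_mean = np.cumsum(cv) / i

    def _running_pop_sd(x: np.ndarray) -> np.ndarray:
        # centering on the first value avoids cancellation at large offsets
        d = x - x[0]
        md = np.cumsum(d) / i
        return np.sqrt(np.maximum(np.cumsum(d * d) / i - md * md, 0.0))

    hhmm = _running_pop_sd(wm)  # grand mean == mean of window means (equal N)
    return pd.DataFrame({
        "CV_T_mean": cv_mean,
        "CV_T_SD": _running_pop_sd(cv),
        "SD_T_hhmm": hhmm,
    })


def compute_metric_series(
    windows: WindowSet,
    r1: float = R1_MAX_C,
    r2: float = R2_MEAN_C,
    literal_cube_inside_log: bool = False,
) -> pd.DataFrame:
    """All 12 metrics for every retained window of one subject.

    Returns a tidy frame with one row per retained window: ``index_i``
    (1-based, contiguous, chronological), ``cgm_timestamp``, ``glucose``, the
    9 current metrics and the 3 retrospective metrics. Retrospective history
    runs over retained windows only, spanning the whole recording.
    """
    ws = windows.retained()
    order = np.argsort(ws.cgm_timestamps.asi8, kind="stable")
    ts = ws.cgm_timestamps[order]
    glucose = ws.glucose[order]
    if len(ws) == 0:
        cols = ["index_i", "cgm_timestamp", "glucose"] + ALL_METRIC_NAMES
        return pd.DataFrame(columns=cols)
    cur = current_metrics_block(ws.samples[order], r1, r2, literal_cube_inside_log)
    retro = retrospective_metrics_series(cur)
    out = pd.concat(
        [
            pd.DataFrame({
                "index_i": np.arange(1, len(ws) + 1),
                "cgm_timestamp": ts,
                "glucose": glucose,
            }),
            cur, retro,
        ],
        axis=1,
    )
    out.insert(0, "subject_id", ws.subject_id)
    return out
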