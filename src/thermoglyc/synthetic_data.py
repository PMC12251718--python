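"""Synthetic paired CGM + 4 Hz wrist-temperature recordings with ground truth.

The generator emulates the structure the analysis pipeline assumes, so every
stage is testable without any real deposit:

* a multi-day monitoring span (default 9 days, within the 8-10 day protocol
  range) with a 5-min CGM cadence and a 4 Hz skin-temperature stream;
* glucose as a label-generating process — a flat baseline plus smooth meal
  excursions that cross the 140 mg/dL bound, optional hypoglycemic episodes
  dipping below 70 mg/dL, and white measurement noise — not a metabolic
  simulation;
* temperature as a circadian day/night level profile (night above day, the
  distal-skin sleep-onset rise) plus slow AR(1) noise;
* injectable defects with per-window ground-truth labels: sub-28 °C artifact
  segments, isolated > 5 SD outlier spikes, under-filled (missing-sample)
  windows and empty-valued CGM rows;
* configurable couplings between glycemia and temperature: a within-window
  noise-SD multiplier during below-range (BR) episodes (``cv_effect``), a
  daytime level shift during above-range (AR) windows (``level_effect_day``)
  and a slow nighttime AR drift (``retro_effect``). With all couplings at
  their neutral values the temperature stream is generated independently of
  the glucose labels.

The temperature grid starts 300 s before the first CGM timestamp so that
every CGM sample owns a complete backward window; all output is fully
determined by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data_io import CGM_FILENAME, TEMP_FILENAME, CGMTrace, TemperatureTrace, write_trace_csv

logger = logging.getLogger(__name__)

GROUND_TRUTH_FILENAME = "ground_truth.csv"

#: per-window defect codes in the sidecar, in preprocessing precedence order
DEFECT_NONE = "none"
DEFECT_CGM_MISSING = "cgm_missing"
DEFECT_TEMP_MISSING = "temp_missing"
DEFECT_ARTIFACT = "artifact"
DEFECT_OUTLIER = "outlier"


@dataclass
class SynthConfig:
    """Cohort-level generator settings.

    Rates are fractions in [0, 1] unless the name says percent. Defaults
    describe a cohort of non-diabetic subjects at risk: glucose mostly in
    the tight range with postprandial excursions above 140 mg/dL, and
    hypoglycemia confined to a subset of subjects.
    """

    n_subjects: int = 15
    days: float = 9.0
    cgm_period_s: int = 300
    temp_hz: int = 4
    start_time: str = "2024-03-04 00:00:00"

    # glucose process (mg/dL). "episodic" builds smooth meal excursions and
    # contiguous hypoglycemic episodes; "exchangeable" draws each sample's
    # glycemic state independently given its day/night period, which makes the
    # label sequence exchangeable within periods — the calibration condition
    # for the rank-sum stage's type-I error, used by null-cohort studies.
    glucose_label_mode: str = "episodic"
    glucose_baseline: float = 105.0
    glucose_noise_sd: float = 5.0
    meals_per_day: int = 3
    meal_hours: tuple = (8.0, 13.0, 19.0)
    meal_hour_jitter_sd: float = 0.7
    meal_amplitude_mean: float = 50.0
    meal_amplitude_sd: float = 15.0
    meal_duration_min: float = 100.0

    # hypoglycemic episodes (assigned to a subject subset)
    n_hypo_subjects: int = 6
    hypo_episodes_per_day: float = 0.5
    hypo_duration_min: float = 35.0
    hypo_nadir_mg_dl: float = 60.0

    # exchangeable-mode per-sample state probabilities (day, night)
    p_above_range: tuple = (0.15, 0.08)
    p_below_range: tuple = (0.05, 0.04)

    # temperature process (°C); night above day (distal circadian rise)
    temp_day_c: float = 31.5
    temp_night_c: float = 33.5
    subject_level_sd_c: float = 0.3  # between-subject baseline spread
    night_start_hour: float = 21.0
    night_end_hour: float = 6.0
    transition_min: float = 30.0
    ar1_coef: float = 0.97
    ar1_innovation_sd: float = 0.08

    # injected defects (per eligible window)
    artifact_rate: float = 0.0
    outlier_rate: float = 0.0
    temp_missing_rate: float = 0.0
    cgm_missing_pct: float = 0.0

    # glycemia -> temperature couplings (neutral values = no coupling)
    cv_effect: float = 1.0
    level_effect_day_c: float = 0.0
    retro_effect_c_per_h: float = 0.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("artifact_rate", "outlier_rate", "temp_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.cgm_missing_pct <= 100:
            raise ValueError("cgm_missing_pct must be in [0, 100]")
        if not self.temp_night_c > self.temp_day_c:
            raise ValueError("night temperature level must exceed day level")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")

    @property
    def n_cgm(self) -> int:
        return int(self.days * 86400 // self.cgm_period_s) + 1

    @property
    def samples_per_window(self) -> int:
        return self.cgm_period_s * self.temp_hz

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "meal_hours" in known:
            known["meal_hours"] = tuple(known["meal_hours"])
        return cls(**known)


@dataclass
class SynthSubject:
    """One generated subject: traces plus per-window ground truth.

    ``truth`` has one row per CGM grid point: timestamp, emitted glucose
    (NaN when the value cell is empty), the glycemic label implied by the
    emitted glucose, the injected defect code and whether the subject was
    assigned hypoglycemic episodes.
    """

    subject_id: str
    cgm: CGMTrace
    temp: TemperatureTrace
    truth: pd.DataFrame
    episodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    has_hypo: bool = False


def _glucose_labels(glucose: np.ndarray) -> np.ndarray:
    lab = np.full(len(glucose), "", dtype=object)
    ok = np.isfinite(glucose)
    lab[ok] = np.where(glucose[ok] < 70, "BR", np.where(glucose[ok] > 140, "AR", "IR"))
    return lab


def _exchangeable_glucose(
    config: SynthConfig, rng: np.random.Generator, t_s: np.ndarray, has_hypo: bool
) -> np.ndarray:
    """Per-sample iid glycemic state given period (no serial structure)."""
    start = pd.Timestamp(config.start_time)
    sod = np.mod((start - start.normalize()).total_seconds() + t_s, 86400.0)
    day = (sod >= 6 * 3600) & (sod < 21 * 3600)
    p_ar = np.where(day, *config.p_above_range)
    p_br = np.where(day, *config.p_below_range) if has_hypo else np.zeros(len(t_s))
    u = rng.uniform(size=len(t_s))
    g = np.clip(rng.normal(config.glucose_baseline, 12.0, len(t_s)), 72.0, 138.0)
    ar = u < p_ar
    br = u >= 1.0 - p_br
    g[ar] = rng.uniform(145.0, 210.0, int(ar.sum()))
    g[br] = rng.uniform(48.0, 68.0, int(br.sum()))
    return g


def generate_cgm(
    config: SynthConfig, rng: np.random.Generator, has_hypo: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Glucose on the full 5-min grid plus an episode table.

    Returns the glucose vector (NaN at empty-valued rows) and a frame of
    injected hypoglycemic episode boundaries.
    """
    n = config.n_cgm
    t_s = np.arange(n) * config.cgm_period_s  # seconds from start
    if config.glucose_label_mode == "exchangeable":
        g = _exchangeable_glucose(config, rng, t_s.astype(float), has_hypo)
        if config.cgm_missing_pct > 0:
            n_miss = int(round(config.cgm_missing_pct / 100.0 * n))
            if n_miss:
                g[rng.choice(n, size=n_miss, replace=False)] = np.nan
        return g, pd.DataFrame(columns=["start_s", "end_s", "kind"])
    if config.glucose_label_mode != "episodic":
        raise ValueError(f"unknown glucose_label_mode {config.glucose_label_mode!r}")
    g = np.full(n, config.glucose_baseline, dtype=float)

    # smooth meal excursions: Gaussian bumps in time
    n_days = int(np.ceil(config.days))
    width_s = config.meal_duration_min * 60.0 / 4.0  # bump SD; ~full width = duration
    for day in range(n_days):
        for h in config.meal_hours[: config.meals_per_day]:
            center = (day * 24 + h + rng.normal(0, config.meal_hour_jitter_sd)) * 3600.0
            amp = max(0.0, rng.normal(config.meal_amplitude_mean, config.meal_amplitude_sd))
            g += amp * np.exp(-0.5 * ((t_s - center) / width_s) ** 2)
    g += rng.normal(0, config.glucose_noise_sd, n)

    episodes = []
    if has_hypo and config.hypo_episodes_per_day > 0:
        n_epi = max(1, int(rng.poisson(config.hypo_episodes_per_day * config.days)))
        dur_s = config.hypo_duration_min * 60.0
        starts = np.sort(rng.uniform(0, config.days * 86400 - dur_s, n_epi))
        for s in starts:
            mask = (t_s >= s) & (t_s < s + dur_s)
            if not mask.any():
                continue
            # smooth dip to the nadir, guaranteed below 70
            u = (t_s[mask] - s) / dur_s
            depth = config.hypo_nadir_mg_dl + rng.normal(0, 2.0)
            dip = depth + (69.0 - depth) * np.abs(2 * u - 1) ** 2
            g[mask] = np.minimum(g[mask], np.clip(dip, 40.0, 69.0))
            episodes.append({"start_s": float(s), "end_s": float(s + dur_s), "kind": "hypo"})
    g = np.clip(g, 40.0, 400.0)

    # empty-valued rows: timestamps stay, the value cell is blank
    if config.cgm_missing_pct > 0:
        n_miss = int(round(config.cgm_missing_pct / 100.0 * n))
        if n_miss:
            g[rng.choice(n, size=n_miss, replace=False)] = np.nan
    return g, pd.DataFrame(episodes, columns=["start_s", "end_s", "kind"])


def _circadian_profile(seconds_of_day: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Day/night level with sigmoid transitions at the configured hours."""
    w = max(config.transition_min * 60.0 / 4.0, 1.0)
    to_night = 1.0 / (1.0 + np.exp(-(seconds_of_day - config.night_start_hour * 3600) / w))
    to_day = 1.0 / (1.0 + np.exp(-(config.night_end_hour * 3600 - seconds_of_day) / w))
    night_weight = np.clip(to_night + to_day, 0.0, 1.0)
    return config.temp_day_c + (config.temp_night_c - config.temp_day_c) * night_weight


def generate_temperature(
    config: SynthConfig,
    glucose: np.ndarray,
    rng: np.random.Generator,
    start: pd.Timestamp,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4 Hz temperature over (start - 300 s, last CGM time], with defects.

    Returns ``(values, keep_mask, defect_codes)`` where ``values`` sits on the
    dense grid, ``keep_mask`` marks samples that survive the missing-block
    deletion, and ``defect_codes`` is the per-CGM-window ground truth.
    """
    n_win = len(glucose)
    spw = config.samples_per_window
    n_temp = n_win * spw
    dt = 1.0 / config.temp_hz

    # seconds-of-day of each sample (start is at local midnight by default);
    # the grid is day-periodic, so the circadian profile is computed for one
    # day and tiled
    start_sod = (start - start.normalize()).total_seconds()
    spd = int(86400 * config.temp_hz)
    m = min(n_temp, spd)
    t_rel0 = -config.cgm_period_s + (np.arange(m) + 1) * dt
    sod0 = np.mod(start_sod + t_rel0, 86400.0)
    reps = -(-n_temp // m)
    base = np.tile(_circadian_profile(sod0, config), reps)[:n_temp]
    sod = np.tile(sod0, reps)[:n_temp]

    labels = _glucose_labels(glucose)
    win_of_sample = np.arange(n_temp) // spw

    innov = rng.standard_normal(n_temp, dtype=np.float32)
    innov *= np.float32(config.ar1_innovation_sd)
    if config.cv_effect != 1.0:
        br_samples = np.isin(win_of_sample, np.flatnonzero(labels == "BR"))
        innov[br_samples] *= np.float32(config.cv_effect)
    stat_sd = config.ar1_innovation_sd / np.sqrt(1.0 - config.ar1_coef**2)
    x0 = rng.normal(0, stat_sd)  # stationary start, not zero start
    noise, _ = lfilter(
        np.array([1.0], np.float32),
        np.array([1.0, -config.ar1_coef], np.float32),
        innov,
        zi=np.array([config.ar1_coef * x0], np.float32),
    )
    values = base + noise
    values += rng.normal(0, config.subject_level_sd_c)  # subject baseline offset

    day_sample = (sod >= 6 * 3600) & (sod < 21 * 3600)
    if config.level_effect_day_c != 0.0:
        ar_mask = np.isin(win_of_sample, np.flatnonzero(labels == "AR"))
        values[ar_mask & day_sample] += config.level_effect_day_c
    if config.retro_effect_c_per_h != 0.0:
        drift_mask = np.isin(win_of_sample, np.flatnonzero(labels == "AR")) & ~day_sample
        run = np.cumsum(drift_mask) - np.maximum.accumulate(np.where(~drift_mask, np.cumsum(drift_mask), 0))
        values += config.retro_effect_c_per_h * run * dt / 3600.0

    # defect injection into windows whose glucose is present (precedence:
    # a cgm-missing window would mask any other injected defect)
    defects = np.full(n_win, DEFECT_NONE, dtype=object)
    defects[~np.isfinite(glucose)] = DEFECT_CGM_MISSING
    eligible = np.flatnonzero(defects == DEFECT_NONE)
    rng.shuffle(eligible)
    n_art = int(round(config.artifact_rate * len(eligible)))
    n_out = int(round(config.outlier_rate * len(eligible)))
    n_mis = int(round(config.temp_missing_rate * len(eligible)))
    art_w = eligible[:n_art]
    out_w = eligible[n_art : n_art + n_out]
    mis_w = eligible[n_art + n_out : n_art + n_out + n_mis]

    for w in art_w:
        seg_len = int(rng.integers(8, 80))
        off = int(rng.integers(0, spw - seg_len))
        sl = slice(w * spw + off, w * spw + off + seg_len)
        values[sl] = rng.uniform(26.0, 27.8, seg_len)
    defects[art_w] = DEFECT_ARTIFACT

    for w in out_w:
        sl = slice(w * spw, (w + 1) * spw)
        local = values[sl]
        spike = local.mean() + 8.0 * max(local.std(ddof=1), 0.05)
        values[w * spw + int(rng.integers(0, spw))] = spike
    defects[out_w] = DEFECT_OUTLIER

    keep = np.ones(n_temp, dtype=bool)
    for w in mis_w:
        seg_len = int(rng.integers(1, spw))
        off = int(rng.integers(0, spw - seg_len + 1))
        keep[w * spw + off : w * spw + off + seg_len] = False
    defects[mis_w] = DEFECT_TEMP_MISSING

    return values, keep, defects


def generate_subject(
    config: SynthConfig, subject_id: str, rng: np.random.Generator, has_hypo: bool = False
) -> SynthSubject:
    """One fully coupled subject recording with ground-truth sidecar."""
    start = pd.Timestamp(config.start_time)
    glucose, episodes = generate_cgm(config, rng, has_hypo)
    values, keep, defects = generate_temperature(config, glucose, rng, start)

    cgm_times = start + pd.to_timedelta(np.arange(config.n_cgm) * config.cgm_period_s, unit="s")
    dt_ns = int(1e9 / config.temp_hz)
    temp_times = (
        start
        - pd.Timedelta(seconds=config.cgm_period_s)
        + pd.to_timedelta((np.arange(len(values)) + 1) * dt_ns, unit="ns")
    )
    cgm = CGMTrace(subject_id, pd.DatetimeIndex(cgm_times), glucose)
    temp = TemperatureTrace(subject_id, pd.DatetimeIndex(temp_times[keep]), values[keep])
    truth = pd.DataFrame({
        "cgm_timestamp": cgm_times,
        "glucose": glucose,
        "glycemic_label": _glucose_labels(glucose),
        "defect": defects,
    })
    return SynthSubject(subject_id, cgm, temp, truth, episodes, has_hypo)


def generate_cohort_memory(config: SynthConfig) -> list[SynthSubject]:
    """All subjects in memory; seed fully determines every value."""
    root_ss = np.random.SeedSequence(config.rng_seed)
    assign_rng = np.random.default_rng(root_ss.spawn(1)[0])
    n_hypo = min(config.n_hypo_subjects, config.n_subjects)
    hypo_idx = set(assign_rng.choice(config.n_subjects, size=n_hypo, replace=False).tolist())
    subjects = []
    for i, ss in enumerate(root_ss.spawn(config.n_subjects + 1)[1:]):
        sid = f"S{i + 1:02d}"
        subjects.append(generate_subject(config, sid, np.random.default_rng(ss), i in hypo_idx))
    return subjects


def generate_cohort(config: SynthConfig, out_dir: str | Path) -> list[Path]:
    """Write per-subject folders (Dexcom.csv, TEMP.csv, ground-truth sidecar).

    The CSV dialect matches what :mod:`thermoglyc.data_io` reads, so the
    pipeline consumes these folders exactly like real data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    folders = []
    for subj in generate_cohort_memory(config):
        folder = out_dir / subj.subject_id
        folder.mkdir(exist_ok=True)
        write_trace_csv(subj.cgm, folder / CGM_FILENAME)
        write_trace_csv(subj.temp, folder / TEMP_FILENAME)
        truth = subj.truth.copy()
        truth["cgm_timestamp"] = truth["cgm_timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.%f")
        truth.to_csv(folder / GROUND_TRUTH_FILENAME, index=False)
        if len(subj.episodes):
            subj.episodes.to_csv(folder / "episodes.csv", index=False)
        folders.append(folder)
    logger.info("wrote %d synthetic subject folders under %s", len(folders), out_dir)
    return folders


def null_config(**overrides) -> SynthConfig:
    """A no-coupling, defect-free configuration for type-I error studies.

    Uses the exchangeable label mode: rank-based two-sample p-values are only
    calibrated when, within a period, the label sequence is exchangeable and
    independent of the temperature stream, so the null cohort is generated
    under exactly that condition. (With episodic glucose, the serial
    dependence of the retrospective metrics inflates subject-level false
    positives — a caveat that applies to window-level testing on real
    recordings too.)
    """
    base = SynthConfig(
        glucose_label_mode="exchangeable",
        artifact_rate=0.0, outlier_rate=0.0, temp_missing_rate=0.0,
        cgm_missing_pct=0.0, cv_effect=1.0, level_effect_day_c=0.0,
        retro_effect_c_per_h=0.0,
    )
    return replace(base, **overrides)
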