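"""End-to-end orchestration: cohort in, tidy CSVs + rendered tables out.

``run_pipeline`` walks a directory of per-subject folders (real deposit
layout or synthetic), applies subject exclusion, preprocessing, metric
extraction, stratification and both statistical stages, and writes:

* ``preprocess_report.csv``   — one row per subject, discard tallies
* ``metric_series/<id>.csv``  — per-window metrics, tidy
* ``comparisons.csv``         — per-subject Wilcoxon results with FDR
* ``cohort_models.csv``       — LME fixed-effect results with FDR
* ``significance_summary.csv``— percent of eligible subjects per tier
* ``table_<metric>.md``       — subject-by-range median[p25; p75] tables
* ``temperature_histogram.png`` — distribution before/after preprocessing

Rendering is presentation-only: every number in a rendered table is
re-derivable from the tidy CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, metrics, preprocessing, stats, stratification

logger = logging.getLogger(__name__)

#: metrics whose stored values are rescaled for display, with header note
RENDER_SCALE = {"M2_T": (100.0, "M2_T x 10^-2")}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    artifact_floor_c: float = 28.0
    outlier_sd_multiplier: float = 5.0
    cgm_missing_exclusion_pct: float = 20.0
    window_seconds: int = 300
    temp_hz: int = 4
    tight_range_mg_dl: tuple = (70.0, 140.0)
    daytime_hours: tuple = (6, 21)
    min_group_size: int = 4
    fdr_scope: str = "per_period"
    sqrt_transform: bool = True
    seed: int = 0
    histogram_bin_width_c: float = 0.25

    @property
    def preprocess(self) -> preprocessing.PreprocessConfig:
        return preprocessing.PreprocessConfig(
            artifact_floor_c=self.artifact_floor_c,
            outlier_sd_multiplier=self.outlier_sd_multiplier,
            cgm_missing_exclusion_pct=self.cgm_missing_exclusion_pct,
            window_seconds=self.window_seconds,
            temp_hz=self.temp_hz,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["tight_range_mg_dl"] = list(d["tight_range_mg_dl"])
        d["daytime_hours"] = list(d["daytime_hours"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunResult:
    """In-memory bundle of everything a run computed."""

    reports: pd.DataFrame
    labeled: pd.DataFrame
    comparisons: pd.DataFrame
    cohort_models: pd.DataFrame
    summary: pd.DataFrame
    excluded_subjects: list = field(default_factory=list)
    completeness: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_subject(
    temp: data_io.TemperatureTrace,
    cgm: data_io.CGMTrace,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, preprocessing.PreprocessReport]:
    """Preprocess one subject and compute its labeled metric table."""
    config = config or RunConfig()
    retained, report = preprocessing.preprocess_subject(temp, cgm, config.preprocess)
    series = metrics.compute_metric_series(retained)
    labeled = stratification.stratify(
        series, tuple(config.tight_range_mg_dl), tuple(config.daytime_hours)
    )
    return labeled, report


def analyze_cohort(
    subjects: list[tuple[data_io.CGMTrace, data_io.TemperatureTrace]],
    config: RunConfig | None = None,
) -> RunResult:
    """Full analysis of an in-memory cohort (used by the CLI and by tests)."""
    config = config or RunConfig()
    reports, labeled_parts, excluded, completeness = [], [], [], []
    for cgm, temp in subjects:
        summary = data_io.summarize_completeness(cgm, config.window_seconds)
        completeness.append(summary.__dict__)
        if preprocessing.exclude_subject(summary, config.cgm_missing_exclusion_pct):
            logger.info(
                "excluding subject %s: %.1f%% CGM samples missing",
                cgm.subject_id, summary.percent_missing_cgm,
            )
            excluded.append(cgm.subject_id)
            continue
        labeled, report = analyze_subject(temp, cgm, config)
        reports.append(report.to_row())
        labeled_parts.append(labeled)
    if not labeled_parts:
        raise RuntimeError("no usable subjects after exclusion")
    labeled = pd.concat(labeled_parts, ignore_index=True)
    comparisons = stats.compare_subjects(
        labeled, min_group_size=config.min_group_size, fdr_scope=config.fdr_scope
    )
    cohort_models = stats.run_cohort_models(labeled, sqrt_transform=config.sqrt_transform)
    summary = stats.summarize_significance(comparisons)
    return RunResult(
        reports=pd.DataFrame(reports),
        labeled=labeled,
        comparisons=comparisons,
        cohort_models=cohort_models,
        summary=summary,
        excluded_subjects=excluded,
        completeness=pd.DataFrame(completeness),
    )


def render_subject_table(
    comparisons: pd.DataFrame, metric: str, fmt: str = "markdown"
) -> str:
    """Subject-by-range table: rows subjects, columns IR/AR/BR x day/night.

    Cells are ``median[p25; p75]`` of the metric in that stratum; ``*`` marks
    FDR-corrected p < 0.05 for the contrast against IR; ``-`` marks a subject
    with no windows at that level (mostly BR). Display-scaled metrics carry
    the scale in the header.
    """
    scale, header_metric = RENDER_SCALE.get(metric, (1.0, metric))
    sub = comparisons[comparisons["metric"] == metric] if len(comparisons) else comparisons
    cols = [
        ("daytime", "IR"), ("daytime", "AR"), ("daytime", "BR"),
        ("nighttime", "IR"), ("nighttime", "AR"), ("nighttime", "BR"),
    ]
    period_short = {"daytime": "Day", "nighttime": "Night"}
    header = ["Subject"] + [f"{period_short[p]} {g}" for p, g in cols]
    rows = []
    for sid in sorted(sub["subject_id"].unique()) if len(sub) else []:
        row = {"Subject": sid}
        for period, glabel in cols:
            cell = "-"
            per = sub[(sub["subject_id"] == sid) & (sub["period"] == period)]
            if glabel == "IR":
                if len(per):
                    r = per.iloc[0]
                    cell = _fmt_cell(r["ref_median"], r["ref_p25"], r["ref_p75"], scale)
            else:
                contrast = f"{glabel}_vs_IR"
                hit = per[per["contrast"] == contrast]
                if len(hit):
                    r = hit.iloc[0]
                    cell = _fmt_cell(r["alt_median"], r["alt_p25"], r["alt_p75"], scale)
                    if r["p_fdr"] < stats.ALPHA:
                        cell += " *"
            row[f"{period_short[period]} {glabel}"] = cell
        rows.append(row)
    table = pd.DataFrame(rows, columns=header)
    title = f"{header_metric} — median[p25; p75] by glycemic range and period"
    if fmt == "markdown":
        return f"### {title}\n\n" + table.to_markdown(index=False)
    if fmt == "csv":
        return table.to_csv(index=False)
    raise ValueError(f"unknown table format {fmt!r}")


def _fmt_cell(med: float, p25: float, p75: float, scale: float) -> str:
    return f"{med * scale:.3g}[{p25 * scale:.3g}; {p75 * scale:.3g}]"


def temperature_histogram(
    before: np.ndarray, after: np.ndarray, path: str | Path,
    bin_width: float = 0.25, floor: float = 28.0,
) -> None:
    """Before/after-preprocessing temperature histograms with the floor marker."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    before = before[np.isfinite(before)]
    lo = np.floor(min(before.min(), after.min()) / bin_width) * bin_width
    hi = np.ceil(max(before.max(), after.max()) / bin_width) * bin_width
    bins = np.arange(lo, hi + bin_width, bin_width)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.hist(before, bins=bins, alpha=0.6, label="before preprocessing")
    ax.hist(after, bins=bins, alpha=0.6, label="after preprocessing")
    ax.axvline(floor, color="red", linestyle="--", label=f"{floor:g} °C floor")
    ax.set_xlabel("skin temperature (°C)")
    ax.set_ylabel("samples per bin")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> RunResult:
    """Read a cohort directory, analyze it, and write the output bundle."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    folders = sorted(
        p for p in in_dir.iterdir()
        if p.is_dir() and (p / data_io.CGM_FILENAME).exists()
    )
    if not folders:
        raise RuntimeError(f"no subject folders with {data_io.CGM_FILENAME} under {in_dir}")
    logger.info("found %d subject folders under %s", len(folders), in_dir)
    subjects = [data_io.read_subject_folder(f) for f in folders]
    result = analyze_cohort(subjects, config)

    config.to_yaml(out_dir / "run_config.yaml")
    result.reports.to_csv(out_dir / "preprocess_report.csv", index=False)
    result.completeness.to_csv(out_dir / "completeness.csv", index=False)
    series_dir = out_dir / "metric_series"
    series_dir.mkdir(exist_ok=True)
    for sid, sub in result.labeled.groupby("subject_id"):
        sub.to_csv(series_dir / f"{sid}.csv", index=False)
    result.comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    result.cohort_models.to_csv(out_dir / "cohort_models.csv", index=False)
    result.summary.to_csv(out_dir / "significance_summary.csv", index=False)
    for metric in ("M2_T", "CV_T_mean", "CV_T_SD", "SD_T_hhmm"):
        text = render_subject_table(result.comparisons, metric, fmt="markdown")
        (out_dir / f"table_{metric}.md").write_text(text + "\n")

    # histogram of raw vs retained temperature samples
    before = np.concatenate([t.values for _, t in subjects])
    after_parts = []
    for cgm, temp in subjects:
        summary = data_io.summarize_completeness(cgm, config.window_seconds)
        if preprocessing.exclude_subject(summary, config.cgm_missing_exclusion_pct):
            continue
        retained, _ = preprocessing.preprocess_subject(temp, cgm, config.preprocess)
        if len(retained):
            after_parts.append(retained.samples.ravel())
    after = np.concatenate(after_parts) if after_parts else np.array([])
    if after.size:
        temperature_histogram(
            before, after, out_dir / "temperature_histogram.png",
            bin_width=config.histogram_bin_width_c, floor=config.artifact_floor_c,
        )
    logger.info(
        "run complete: %d subjects analyzed, %d excluded, %d comparison rows",
        result.reports.shape[0], len(result.excluded_subjects), len(result.comparisons),
    )
    return result
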