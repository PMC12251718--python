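"""Per-subject nonparametric comparisons and cohort-level mixed-effects models.

For each subject, metric, contrast (AR vs IR, BR vs IR) and period (day,
night), metric values are compared with a two-sided Wilcoxon rank-sum test
(exact null distribution when n+m <= 25 with no ties, normal approximation
with midrank tie correction otherwise); raw p-values are corrected with the
Benjamini-Hochberg step-up FDR procedure across the metric family within each
(subject, contrast, period) cell. Groups below the minimum size (default 4,
the smallest at which a two-sided exact rank-sum test can reach p < 0.05)
yield no result rather than a fabricated one.

At the cohort level a linear mixed-effects model with glycemic level as a
fixed effect (IR as reference) and a per-subject random intercept is fitted
by maximum likelihood to square-root-transformed metric values; fixed-effect
p-values are FDR-corrected across metrics within each contrast and period.

Normality screening uses the Lilliefors test (Kolmogorov-Smirnov with
estimated mean and variance); it gates reporting only — the subject-level
analysis is always nonparametric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .metrics import ALL_METRIC_NAMES
from .stratification import GlycemicLabel, PeriodLabel

logger = logging.getLogger(__name__)

CONTRASTS = {"AR_vs_IR": GlycemicLabel.AR, "BR_vs_IR": GlycemicLabel.BR}
MIN_GROUP_SIZE = 4
EXACT_MAX_N = 25
ALPHA = 0.05
STRONG_P = 0.01


def significance_tier(p: float) -> str:
    """'strong' for p < 0.01, 'moderate' for 0.01 <= p < 0.05, else 'none'."""
    if p < STRONG_P:
        return "strong"
    if p < ALPHA:
        return "moderate"
    return "none"


def lilliefors_test(values: np.ndarray) -> float | None:
    """Lilliefors normality p-value; None for n < 5 or degenerate input."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5 or np.ptp(x) == 0:
        return None
    _, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def _quartile_summary(x: np.ndarray) -> tuple[float, float, float]:
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q25), float(q75)


def wilcoxon_compare(
    ref: np.ndarray, alt: np.ndarray, min_group_size: int = MIN_GROUP_SIZE
) -> dict | None:
    """Two-sided rank-sum p and median [p25; p75] summaries, or None.

    None mirrors the "-" cells of a results table: a group below the minimum
    size supports no test.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if len(ref) < min_group_size or len(alt) < min_group_size:
        return None
    pooled = np.concatenate([ref, alt])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(alt, ref, alternative="two-sided", method=method)
    med_r, q25_r, q75_r = _quartile_summary(ref)
    med_a, q25_a, q75_a = _quartile_summary(alt)
    return {
        "p_raw": float(min(res.pvalue, 1.0)),
        "n_ref": len(ref),
        "n_alt": len(alt),
        "ref_median": med_r, "ref_p25": q25_r, "ref_p75": q75_r,
        "alt_median": med_a, "alt_p25": q25_a, "alt_p75": q75_a,
    }


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def compare_subjects(
    labeled: pd.DataFrame,
    metric_names: list[str] | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
    fdr_scope: str = "per_period",
) -> pd.DataFrame:
    """Per-subject Wilcoxon comparisons for every metric/contrast/period.

    ``labeled`` is a stratified metric table (possibly several subjects). FDR
    scope ``per_period`` corrects across metrics within each
    (subject, contrast, period) cell; ``pooled_periods`` pools the day and
    night p-values of a (subject, contrast) pair into one family.
    """
    if fdr_scope not in ("per_period", "pooled_periods"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    metric_names = metric_names or ALL_METRIC_NAMES
    rows = []
    for (sid, period), sub in labeled.groupby(["subject_id", "period"], observed=True):
        ir = sub[sub["glycemic_label"] == GlycemicLabel.IR.value]
        for contrast, alt_label in CONTRASTS.items():
            alt = sub[sub["glycemic_label"] == alt_label.value]
            for metric in metric_names:
                res = wilcoxon_compare(
                    ir[metric].to_numpy(), alt[metric].to_numpy(), min_group_size
                )
                if res is None:
                    continue
                rows.append({
                    "subject_id": sid, "metric": metric,
                    "contrast": contrast, "period": period, **res,
                })
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    group_cols = ["subject_id", "contrast"] + (
        ["period"] if fdr_scope == "per_period" else []
    )
    out["p_fdr"] = (
        out.groupby(group_cols, observed=True)["p_raw"].transform(lambda p: bh_fdr(p.to_numpy()))
    )
    out["significant"] = out["p_fdr"] < ALPHA
    out["tier"] = out["p_fdr"].map(significance_tier)
    return out


@dataclass
class CohortModelResult:
    metric: str
    contrast: str
    period: str
    estimate: float
    p_raw: float
    n_subjects: int
    n_windows: int
    transform: str = "sqrt"
    converged: bool = True
    singular: bool = False


def fit_cohort_model(
    labeled: pd.DataFrame,
    metric: str,
    contrast: str,
    period: str,
    sqrt_transform: bool = True,
) -> CohortModelResult | None:
    """Random-intercept LME of one metric on glycemic level, ML fit.

    Model: sqrt(metric) ~ level + (1 | subject), level coded 0 for IR
    (reference) and 1 for the contrast's non-IR label. Returns None when
    fewer than two subjects contribute both levels (random intercept and
    fixed effect are then not jointly identifiable).
    """
    alt_label = CONTRASTS[contrast].value
    sub = labeled[
        (labeled["period"] == period)
        & (labeled["glycemic_label"].isin([GlycemicLabel.IR.value, alt_label]))
    ]
    if len(sub) == 0:
        return None
    level = (sub["glycemic_label"] == alt_label).astype(float).to_numpy()
    both = sub.groupby("subject_id", observed=True).apply(
        lambda d: d["glycemic_label"].nunique() == 2, include_groups=False
    )
    if int(both.sum()) < 2:
        return None
    y = sub[metric].to_numpy(dtype=float)
    if sqrt_transform:
        if (y < 0).any():
            raise ValueError(f"{metric}: negative values, sqrt transform undefined")
        y = np.sqrt(y)
    exog = np.column_stack([np.ones_like(level), level])
    groups = sub["subject_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=False, method="lbfgs")
    except (np.linalg.LinAlgError, ValueError) as err:
        logger.warning("cohort LME %s %s %s failed: %s", metric, contrast, period, err)
        return CohortModelResult(
            metric=metric, contrast=contrast, period=period,
            estimate=float("nan"), p_raw=float("nan"),
            n_subjects=int(sub["subject_id"].nunique()), n_windows=len(sub),
            transform="sqrt" if sqrt_transform else "none",
            converged=False, singular=True,
        )
    cov_re = float(np.asarray(fit.cov_re)[0, 0])
    singular = not np.isfinite(fit.pvalues[1]) or cov_re <= 1e-12
    return CohortModelResult(
        metric=metric, contrast=contrast, period=period,
        estimate=float(fit.params[1]),
        p_raw=float(fit.pvalues[1]) if np.isfinite(fit.pvalues[1]) else float("nan"),
        n_subjects=int(sub["subject_id"].nunique()),
        n_windows=len(sub),
        transform="sqrt" if sqrt_transform else "none",
        converged=bool(fit.converged),
        singular=bool(singular),
    )


def run_cohort_models(
    labeled: pd.DataFrame,
    metric_names: list[str] | None = None,
    sqrt_transform: bool = True,
) -> pd.DataFrame:
    """Separate LMEs per contrast/period, FDR-corrected across metrics."""
    metric_names = metric_names or ALL_METRIC_NAMES
    rows = []
    for contrast in CONTRASTS:
        for period in (PeriodLabel.DAYTIME.value, PeriodLabel.NIGHTTIME.value):
            for metric in metric_names:
                res = fit_cohort_model(labeled, metric, contrast, period, sqrt_transform)
                if res is None:
                    continue
                if res.singular:
                    logger.debug(
                        "cohort LME %s %s %s: singular/degenerate fit (flagged)",
                        metric, contrast, period,
                    )
                rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out

    def _bh_skipping_failed_fits(p: pd.Series) -> np.ndarray:
        vals = p.to_numpy(dtype=float)
        adj = np.full_like(vals, np.nan)
        ok = np.isfinite(vals)
        if ok.any():
            adj[ok] = bh_fdr(vals[ok])
        return adj

    out["p_fdr"] = (
        out.groupby(["contrast", "period"], observed=True)["p_raw"]
        .transform(_bh_skipping_failed_fits)
    )
    out["significant"] = out["p_fdr"] < ALPHA
    return out


def summarize_significance(results: pd.DataFrame) -> pd.DataFrame:
    """Percent of eligible subjects significant, per metric/contrast/period.

    Eligible = subjects for which the comparison could be run at all (they
    exhibit the contrast's non-IR level in that period with enough windows);
    cells with zero eligible subjects are simply absent.
    """
    if len(results) == 0:
        return pd.DataFrame(
            columns=["metric", "contrast", "period", "n_eligible", "n_significant",
                     "pct_significant", "n_moderate", "n_strong"]
        )
    rows = []
    for (metric, contrast, period), sub in results.groupby(
        ["metric", "contrast", "period"], observed=True
    ):
        n = len(sub)
        n_sig = int(sub["significant"].sum())
        rows.append({
            "metric": metric, "contrast": contrast, "period": period,
            "n_eligible": n, "n_significant": n_sig,
            "pct_significant": 100.0 * n_sig / n,
            "n_moderate": int((sub["tier"] == "moderate").sum()),
            "n_strong": int((sub["tier"] == "strong").sum()),
        })
    return pd.DataFrame(rows)
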