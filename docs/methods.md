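# Methods

## Problem and pipeline

The package analyzes paired recordings from free-living subjects: interstitial
glucose sampled every 5 min (mg/dL) and wrist skin temperature sampled at
4 Hz (°C). The goal is to quantify, per subject and cohort-wide, whether skin
temperature variability differs between in-range glycemia (IR, 70–140 mg/dL)
and above-/below-range glycemia (AR/BR), separately for daytime and
nighttime.

Processing stages: subject exclusion → backward window alignment → window
screening → metric extraction → glycemic/period stratification → per-subject
rank tests with FDR correction → cohort mixed-effects models.

## Alignment and screening

Each CGM timestamp `t` owns the half-open temperature interval `(t − 300 s, t]`.
Half-openness is a deliberate convention: a sample sitting exactly on a CGM
timestamp belongs to exactly one window. A usable window must contain exactly
N = 1200 samples — no tolerance, because the metric denominators assume fixed
N and no resampling or imputation is performed anywhere.

Verdict precedence is deterministic: missing glucose, then missing
temperature, then artifact (any sample strictly below the 28 °C floor — the
practical lower bound for wrist skin in free-living recordings), then outlier
(any sample strictly outside window mean ± 5 sample SD). Equality at a bound
retains the sample, because the rules are strict inequalities; a constant
window has SD = 0 and passes. The artifact-before-outlier order is observable
only in the discard tally, not in the retained set. Subject exclusion uses a
strictly-greater-than-20 % missing-CGM rule computed on the subject's own
observed first-to-last span (`expected = floor(span/300 s) + 1`); the
alternative protocol-days denominator would only matter for subjects with
large leading/trailing gaps.

## Metrics

Window-local ("current") metrics: mean, median, sample SD (N−1), IQR (linear
interpolation between order statistics), CV = SD/mean, the mean amplitude
deviation `MAD = 1.4826 · mean|st − median|` (1.4826 is the consistency
factor for normal data), the J-index adaptation `J = 0.001·(mean + SD)²`,
and two M-value adaptations `M = mean |10·log10(st/r)|³` against reference
temperatures r₁ = 36 °C (maximal) and r₂ = 32 °C (typical mean level).

Two notational choices in the M-value needed pinning. The printed form
`|10·log(st/r)^3|` is ambiguous; we cube the absolute deviation — the
convention of the original glycemic M-value this metric adapts — and use
log base 10 for the same reason. A config flag
(`literal_cube_inside_log`) switches to the literal reading
`10·|log10((st/r)³)| = 30·|log10(st/r)|` for sensitivity checks.

Retrospective metrics at window i use retained windows 1..i over the whole
recording (day and night interleaved, no daily reset): the running mean and
running *population* SD (divide by i, exactly as defined, not i−1) of the CV
series, and the running population SD of the window means about the grand
sample mean. With equal-length windows the grand mean equals the mean of
window means; the implementation relies on (and the tests assert) that
identity. Running statistics are computed with first-value-centered
accumulators; the naive sum-of-squares form loses ~7 significant digits at a
32 °C offset and fails the 1e−9 streaming-vs-batch equivalence the tests
demand. Discarded windows contribute nothing to the retrospective history.
M2 values are stored raw; the ×10² display scale is applied only when
rendering tables.

## Stratification

IR is inclusive of 70 and 140 mg/dL (forced by the strict inequalities
defining AR/BR). Daytime is the half-open wall-clock interval
[06:00, 21:00); each boundary instant belongs to the period it opens.
Timestamps are parsed timezone-naive as local clock time, which is what
day/night splitting needs.

## Statistics

Per subject, metric, contrast (AR vs IR, BR vs IR) and period, a two-sided
Wilcoxon rank-sum test compares window-level metric values. The exact null
distribution is used when n+m ≤ 25 with no ties; otherwise the normal
approximation with midrank tie correction. Both groups must have ≥ 4
windows — the smallest size at which a two-sided exact test can reach
p < 0.05 — else the result is absent (rendered as "-"), never fabricated.
Raw p-values are BH-FDR-corrected across the 12-metric family within each
(subject, contrast, period) cell; a pooled-periods scope is available via
config. Significance tiers: moderate 0.01 ≤ p < 0.05, strong p < 0.01, on
corrected p-values.

Cohort-level generalization uses a linear mixed-effects model per metric,
contrast and period: square-root-transformed metric ~ glycemic level (IR as
reference, treatment coding) + per-subject random intercept, fitted by
maximum likelihood. The square-root transform is applied to all metrics by
default (they are non-negative with variance roughly proportional to the
mean); a per-metric override exists. Fits require ≥ 2 subjects contributing
both levels; singular or failed fits are flagged in the output and excluded
from the FDR family (correction across metrics within contrast × period),
never silently dropped. The Lilliefors test (KS with estimated moments) is
available for normality screening of reported distributions; the subject-level
analysis is nonparametric regardless.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, with ground truth
for every window, and writes folders in the same two-column CSV dialect the
readers consume. Defaults describe a 15-subject, 9-day cohort of
non-diabetic subjects at risk (within the 8–10 day protocol range):

- **Glucose (episodic mode, default).** Flat 105 mg/dL baseline, three
  Gaussian meal excursions per day (~8:00, 13:00, 19:00 with 0.7 h jitter,
  amplitude 50 ± 15 mg/dL, ~100 min width) crossing 140 mg/dL, white
  5 mg/dL measurement noise. Hypoglycemic episodes (35 min, nadir
  ~60 mg/dL, guaranteed < 70) are assigned to a random 6-subject subset at
  0.5/day, mirroring a cohort where only some subjects exhibit BR.
  CGM missingness (3 % by default in acceptance studies, matching high
  completeness of real deposits) is emitted as empty value cells so that
  both the completeness computation and the missing-glucose verdict are
  exercised.
- **Temperature.** Day level 31.5 °C, night level 33.5 °C (night above day —
  the distal-skin sleep-onset rise), sigmoid transitions (~30 min) at
  06:00/21:00 so period stratification aligns with the generator's level
  structure, a per-subject baseline offset (SD 0.3 °C), and AR(1) noise
  with coefficient 0.97 at 4 Hz (≈ 8 s correlation time; slow dynamics) and
  innovation SD 0.08 °C (≈ 0.33 °C stationary SD). The grid starts 300 s
  before the first CGM sample so every CGM timestamp owns a complete
  backward window.
- **Defects.** Per-window injection with exact ground-truth labels:
  artifact windows get a sub-28 °C segment, outlier windows a single spike at
  local mean + 8 local SD (which provably exceeds the spike-inclusive
  mean + 5 SD bound at N = 1200), missing windows lose a random block of
  samples. Defect sets are disjoint and only drawn from windows with present
  glucose, so the ground-truth label always equals the verdict the
  preprocessing precedence assigns.
- **Couplings.** `cv_effect` multiplies the AR(1) innovation SD during BR
  windows (the hypoglycemia-variability coupling), `level_effect_day_c`
  shifts daytime AR windows, `retro_effect_c_per_h` adds a slow drift during
  nighttime AR runs. Neutral values (1, 0, 0) decouple temperature from
  glucose entirely.

**Exchangeable null mode.** Rank-sum p-values are exactly calibrated only
when, within a period, the group labels are exchangeable and independent of
the temperature stream. Episodic glucose violates this for the
*retrospective* metrics: they are slowly-varying running statistics, and
meal/episode labels arrive in contiguous runs at recurring clock times, so a
handful of effectively dependent values masquerade as many independent ones
and subject-level false positives inflate well above nominal (we measure
~20 % per retrospective metric at 2-day spans). This is a genuine property
of window-level testing on serially dependent features — it applies to real
recordings as well and is the main statistical caveat of this analysis
design. The generator therefore provides `glucose_label_mode="exchangeable"`
(used by `null_config()`): each CGM sample's glycemic state is drawn
independently given its period. Under that null the Wilcoxon+FDR stage and
the mixed-model stage are calibrated, which is what the null-cohort
studies verify. Passing those studies demonstrates the machinery is
calibrated under exchangeability; it does not certify window-level p-values
on strongly autocorrelated retrospective metrics with clustered episodes.

The generator is a label-generating process, not a metabolic simulation: no
glucose–insulin dynamics, no ambient-temperature confounding, no
accelerometry-based sleep/wake estimation (clock-time day/night is used, as
in the analysis it supports).

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` choose sizes that make the
Monte-Carlo answers stable while keeping runs desk-scale: the null
calibration uses 15-subject cohorts at a reduced 2-day span (200 replicates
in the test suite, 40 in the acceptance script); effect recovery uses
full 9-day cohorts with `cv_effect = 3` and ~1 hypoglycemic episode per day
so affected subjects have ≥ 30 BR windows (4 cohort seeds in the suite, 2 in
the script); the metric oracle check uses 100 random 1200-sample windows at
1e−9 relative tolerance.

## Known limitations

- Retrospective metrics never forget: a variability burst permanently raises
  CV_T SD's level for the rest of the recording. A `reset_daily` variant was
  considered and rejected to keep the running definitions exact; the
  whole-recording convention is part of the metric definitions.
- The per-subject Wilcoxon stage treats windows as independent; see the
  exchangeable-null discussion above for why that is optimistic on
  retrospective metrics.
- The 20 % subject-exclusion denominator uses the observed span; deposits
  with protocol-defined spans may count differently.
- Only the two-column CSV frame dialect is read; raw device session formats
  (start-time + rate headers) are out of scope.
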