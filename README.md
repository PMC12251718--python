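# thermoglyc

Wrist skin-temperature variability as a digital biomarker of glycemia.

Continuous glucose monitors (CGM) report interstitial glucose every 5 min;
wrist-worn wearables such as the Empatica E4 record distal skin temperature at
4 Hz. Skin temperature responds to glycemic state — vasoconstriction during
hypoglycemia, splanchnic blood-flow shifts after meals — so engineered
temperature features are candidate non-invasive markers of glycemic events.
`thermoglyc` implements a complete analysis pipeline for paired CGM +
temperature recordings:

1. **Alignment** — the 4 Hz stream is cut into 5-min windows backward of each
   CGM timestamp; a complete window holds N = 5 × 60 × 4 = 1200 samples.
2. **Screening** — subjects with > 20 % missing CGM samples are excluded;
   windows are discarded for missing glucose, missing temperature samples,
   sub-28 °C artifacts, or samples outside mean ± 5 SD (window-local).
3. **Metrics** — per retained window *i* with samples st<sub>i1</sub>…st<sub>iN</sub>:

   current behavior (window-local):
   mean, median, SD, IQR, CV = SD/mean, and

   - MAD<sub>Ti</sub> = 1.4826 · Σ|st<sub>ik</sub> − median<sub>Ti</sub>| / N
   - J<sub>Ti</sub> = 0.001 · (mean<sub>Ti</sub> + SD<sub>Ti</sub>)²
   - M1<sub>Ti</sub>, M2<sub>Ti</sub> = Σ|10·log₁₀(st<sub>ik</sub>/r)|³ / N with
     r₁ = 36 °C, r₂ = 32 °C

   retrospective behavior (windows 1…i, population denominator *i*):

   - CV<sub>Ti</sub> mean, CV<sub>Ti</sub> SD — running mean / SD of the CV series
   - SD<sub>Ti</sub> hhmm — running SD of the window means about the grand mean

4. **Stratification** — windows are labelled in range (IR, 70–140 mg/dL,
   the time-in-tight-range convention), above range (AR, > 140) or below
   range (BR, < 70), and daytime [06:00, 21:00) vs nighttime.
5. **Statistics** — per subject: two-sided Wilcoxon rank-sum of AR/BR vs IR
   per metric and period, Benjamini–Hochberg FDR across metrics; cohort-wide:
   linear mixed-effects model of each (square-root-transformed) metric on
   glycemic level with a per-subject random intercept.

A seeded synthetic-cohort generator emulates the paired recordings —
circadian day/night temperature levels, AR(1) noise, artifact/outlier/missing
defects with ground-truth labels, meal and hypoglycemia episodes, and
configurable glycemia→temperature couplings — so the full pipeline is
testable without any data download. Real per-subject folders in the
`Dexcom.csv` / `TEMP.csv` two-column dialect are consumed identically.

## Worked example

```sh
thermoglyc synth --out cohort --seed 5 --subjects 3 --days 2
thermoglyc run --input cohort --out results
thermoglyc report --results results --metric CV_T_SD
```

which prints (seed 5):

```
analyzed 3 subjects (0 excluded); outputs in results
### CV_T_SD — median[p25; p75] by glycemic range and period

| Subject   | Day IR                    | Day AR                    | Day BR                      | Night IR                   | Night AR   | Night BR                      |
|:----------|:--------------------------|:--------------------------|:----------------------------|:---------------------------|:-----------|:------------------------------|
| S01       | 0.00114[0.00113; 0.00115] | 0.00114[0.00114; 0.00115] | -                           | 0.00114[0.000994; 0.00114] | -          | 0.00099[0.000982; 0.000991] * |
| S02       | 0.00117[0.00116; 0.0012]  | 0.00117[0.00115; 0.00122] | 0.00121[0.00119; 0.00124] * | -                          | -          | -                             |
| S03       | 0.00119[0.00117; 0.00119] | 0.00118[0.00117; 0.00119] | -                           | 0.00119[0.00111; 0.0012]   | -          | 0.0012[0.0012; 0.0012] *      |
```

Each cell is the metric's median [25th; 75th percentile] over that subject's
windows in that glycemic range and period; `*` marks an
FDR-corrected rank-sum p < 0.05 against the IR windows of the same period,
and `-` a stratum with too few windows to test. This example cohort has no
injected glycemia–temperature coupling, so the starred retrospective-metric
cells are false positives — `docs/methods.md` discusses why window-level
rank tests are optimistic on running (retrospective) metrics when glycemic
episodes cluster in time. `results/` also
holds the tidy CSVs every rendered number derives from
(`comparisons.csv`, `cohort_models.csv`, `significance_summary.csv`,
per-subject metric series) and a before/after preprocessing temperature
histogram.

From Python the same run is:

```python
from thermoglyc import SynthConfig, generate_cohort_memory, analyze_cohort

subs = generate_cohort_memory(SynthConfig(n_subjects=3, days=2.0, rng_seed=5))
result = analyze_cohort([(s.cgm, s.temp) for s in subs])
print(result.summary)          # percent of eligible subjects significant
```

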