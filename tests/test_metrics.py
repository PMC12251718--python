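"""Metric implementations against independent naive re-evaluations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from thermoglyc import metrics as tm
from thermoglyc.preprocessing import Verdict, WindowSet


# --- independent naive oracle: scalar loops, no shared code with the package ---

def naive_current(samples, r1=36.0, r2=32.0):
    n = len(samples)
    mean = sum(samples) / n
    med = float(np.percentile(samples, 50))
    sd = math.sqrt(sum((x - mean) ** 2 for x in samples) / (n - 1)) if n > 1 else 0.0
    iqr = float(np.percentile(samples, 75) - np.percentile(samples, 25))
    mad = 1.4826 * sum(abs(x - med) for x in samples) / n
    j = 0.001 * (mean + sd) ** 2
    m1 = sum(abs(10 * math.log10(x / r1)) ** 3 for x in samples) / n
    m2 = sum(abs(10 * math.log10(x / r2)) ** 3 for x in samples) / n
    return {
        "mean_T": mean, "median_T": med, "SD_T": sd, "IQR_T": iqr,
        "CV_T": sd / mean, "MAD_T": mad, "J_T": j, "M1_T": m1, "M2_T": m2,
    }


def naive_retrospective(cv_hist, mean_hist):
    i = len(cv_hist)
    cv_mean = sum(cv_hist) / i
    cv_sd = math.sqrt(sum((c - cv_mean) ** 2 for c in cv_hist) / i)
    m = sum(mean_hist) / i
    hhmm = math.sqrt(sum((w - m) ** 2 for w in mean_hist) / i)
    return {"CV_T_mean": cv_mean, "CV_T_SD": cv_sd, "SD_T_hhmm": hhmm}


class TestCurrentMetrics:
    def test_matches_naive_oracle_on_random_windows(self, rng):
        for _ in range(25):
            s = 30.0 + rng.uniform(0, 6) + rng.normal(0, rng.uniform(0.01, 1.0), 1200)
            got = tm.current_metrics(s)
            want = naive_current(list(s))
            for k, v in want.items():
                assert getattr(got, k) == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_constant_window_at_reference_32(self):
        got = tm.current_metrics(np.full(1200, 32.0))
        assert got.SD_T == got.CV_T == got.MAD_T == got.IQR_T == 0.0
        assert got.M2_T == 0.0
        assert got.J_T == pytest.approx(0.001 * 32.0**2)  # = 1.024

    def test_constant_window_at_reference_36(self):
        got = tm.current_metrics(np.full(1200, 36.0))
        assert got.M1_T == 0.0

    def test_toy_three_sample_window(self):
        # (31, 32, 33): hand evaluation of every formula
        got = tm.current_metrics(np.array([31.0, 32.0, 33.0]))
        assert got.median_T == 32.0
        assert got.MAD_T == pytest.approx(1.4826 * 2 / 3)   # ~0.9884
        assert got.SD_T == pytest.approx(1.0)
        assert got.J_T == pytest.approx(0.001 * 33.0**2)    # 1.089
        m2 = (abs(10 * math.log10(31 / 32)) ** 3 + 0.0
              + abs(10 * math.log10(33 / 32)) ** 3) / 3
        assert got.M2_T == pytest.approx(m2, rel=1e-12)

    def test_m_value_zero_iff_constant_at_reference(self, rng):
        s = np.full(100, 32.0)
        assert tm.current_metrics(s).M2_T == 0.0
        s[0] = 32.5
        assert tm.current_metrics(s).M2_T > 0.0

    def test_m_value_monotone_away_from_reference(self):
        vals = [tm.current_metrics(np.full(10, v)).M2_T for v in (32.5, 33.5, 35.0, 36.5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        below = [tm.current_metrics(np.full(10, v)).M2_T for v in (31.5, 30.5, 29.0)]
        assert all(b > a for a, b in zip(below, below[1:]))

    def test_nonfinite_sample_rejected(self):
        s = np.full(1200, 32.0)
        s[5] = np.nan
        with pytest.raises(ValueError):
            tm.current_metrics(s)

    @given(shift=hst.floats(-2.0, 10.0), seed=hst.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_behavior(self, shift, seed):
        rng = np.random.default_rng(seed)
        s = 32.0 + rng.normal(0, 0.3, 300)
        a = tm.current_metrics(s)
        b = tm.current_metrics(s + shift)
        assert b.mean_T == pytest.approx(a.mean_T + shift, rel=1e-12)
        assert b.median_T == pytest.approx(a.median_T + shift, rel=1e-9, abs=1e-9)
        assert b.SD_T == pytest.approx(a.SD_T, rel=1e-9)
        assert b.IQR_T == pytest.approx(a.IQR_T, rel=1e-6, abs=1e-9)
        assert b.MAD_T == pytest.approx(a.MAD_T, rel=1e-6, abs=1e-9)
        assert b.CV_T == pytest.approx(b.SD_T / b.mean_T, rel=1e-12)
        assert b.J_T == pytest.approx(0.001 * (b.mean_T + b.SD_T) ** 2, rel=1e-12)


class TestRetrospective:
    def test_single_window_history(self):
        assert tm.retrospective_cv([0.03]) == (pytest.approx(0.03), 0.0)
        assert tm.sd_hhmm([32.0]) == 0.0

    def test_two_value_history(self):
        mean, sd = tm.retrospective_cv([0.02, 0.04])
        assert mean == pytest.approx(0.03)
        assert sd == pytest.approx(0.01)  # population denominator i = 2
        assert tm.sd_hhmm([32.0, 34.0]) == pytest.approx(1.0)

    def test_constant_history_has_zero_spread(self, rng):
        c = float(rng.uniform(0.01, 0.5))
        mean, sd = tm.retrospective_cv([c] * 7)
        assert mean == pytest.approx(c)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert tm.sd_hhmm([33.3] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            tm.retrospective_cv([])
        with pytest.raises(ValueError):
            tm.sd_hhmm([])

    def test_streaming_equals_batch_recompute(self, rng):
        cur = pd.DataFrame({
            "CV_T": rng.uniform(0.001, 0.05, 200),
            "mean_T": 32 + rng.normal(0, 1, 200),
        })
        stream = tm.retrospective_metrics_series(cur)
        for i in (1, 2, 50, 200):
            want = naive_retrospective(
                list(cur["CV_T"][:i]), list(cur["mean_T"][:i])
            )
            row = stream.iloc[i - 1]
            for k, v in want.items():
                assert row[k] == pytest.approx(v, rel=1e-9, abs=1e-12), (k, i)

    def test_grand_mean_equals_mean_of_window_means(self, rng):
        # equal-length windows: m over all samples == mean of window means
        samples = 32 + rng.normal(0, 0.3, (6, 1200))
        wm = samples.mean(axis=1)
        assert tm.sd_hhmm(wm) == pytest.approx(
            tm.sd_hhmm(wm, grand_mean=samples.mean()), rel=1e-12
        )


class TestMetricSeries:
    @staticmethod
    def window_set(rng, n=5, glucose=None):
        start = pd.Timestamp("2024-03-04 09:00:00")
        ts = pd.DatetimeIndex(start + pd.to_timedelta(np.arange(n) * 300, unit="s"))
        g = np.full(n, 100.0) if glucose is None else np.asarray(glucose, float)
        samples = 32.0 + rng.normal(0, 0.2, (n, 1200))
        verdicts = np.array([Verdict.RETAINED.value] * n, dtype=object)
        return WindowSet("S", ts, g, samples, verdicts)

    def test_single_window_series(self, rng):
        out = tm.compute_metric_series(self.window_set(rng, n=1))
        assert len(out) == 1
        assert out.loc[0, "CV_T_SD"] == 0.0
        assert out.loc[0, "SD_T_hhmm"] == 0.0
        assert out.loc[0, "CV_T_mean"] == out.loc[0, "CV_T"]

    def test_composition_matches_direct_calls(self, rng):
        ws = self.window_set(rng, n=4)
        out = tm.compute_metric_series(ws)
        cvs, wms = out["CV_T"].tolist(), out["mean_T"].tolist()
        for i in range(1, 5):
            mean, sd = tm.retrospective_cv(cvs[:i])
            assert out.loc[i - 1, "CV_T_mean"] == pytest.approx(mean, rel=1e-12)
            assert out.loc[i - 1, "CV_T_SD"] == pytest.approx(sd, rel=1e-9, abs=1e-15)
            assert out.loc[i - 1, "SD_T_hhmm"] == pytest.approx(
                tm.sd_hhmm(wms[:i]), rel=1e-9, abs=1e-15)

    def test_input_order_irrelevant(self, rng):
        ws = self.window_set(rng, n=6)
        perm = np.array([3, 0, 5, 1, 4, 2])
        shuffled = WindowSet("S", ws.cgm_timestamps[perm], ws.glucose[perm],
                             ws.samples[perm], ws.verdicts[perm])
        a = tm.compute_metric_series(ws)
        b = tm.compute_metric_series(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_series(self):
        ws = WindowSet("S", pd.DatetimeIndex([]), np.array([]),
                       np.empty((0, 1200)), np.array([], dtype=object))
        out = tm.compute_metric_series(ws)
        assert len(out) == 0
        assert set(tm.ALL_METRIC_NAMES) <= set(out.columns)
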