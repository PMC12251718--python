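import numpy as np
import pandas as pd
import pytest

from thermoglyc import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


def make_trace_pair(
    n_windows=12,
    glucose=None,
    temp_level=32.0,
    temp_noise_sd=0.1,
    start="2024-03-04 00:00:00",
    seed=0,
):
    """Hand-built CGM/temperature pair where every window is fully sampled.

    The temperature grid covers (start - 300 s, last CGM time] at 4 Hz so the
    backward window of every CGM sample holds exactly 1200 samples.
    """
    from thermoglyc.data_io import CGMTrace, TemperatureTrace

    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    cgm_times = start + pd.to_timedelta(np.arange(n_windows) * 300, unit="s")
    if glucose is None:
        glucose = np.full(n_windows, 100.0)
    glucose = np.asarray(glucose, dtype=float)
    n_temp = n_windows * 1200
    temp_times = start - pd.Timedelta(seconds=300) + pd.to_timedelta(
        (np.arange(n_temp) + 1) * 250, unit="ms"
    )
    temp_vals = temp_level + rng.normal(0, temp_noise_sd, n_temp)
    return (
        CGMTrace("T01", pd.DatetimeIndex(cgm_times), glucose),
        TemperatureTrace("T01", pd.DatetimeIndex(temp_times), temp_vals),
    )


@pytest.fixture
def trace_pair():
    return make_trace_pair()


@pytest.fixture(scope="session")
def small_cohort():
    """Three half-day subjects with defects and hypoglycemia, in memory."""
    cfg = sd.SynthConfig(
        n_subjects=3, days=0.5, rng_seed=11,
        n_hypo_subjects=2, hypo_episodes_per_day=4.0,
        artifact_rate=0.05, outlier_rate=0.02,
        temp_missing_rate=0.03, cgm_missing_pct=2.0,
    )
    return sd.generate_cohort_memory(cfg)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A tiny on-disk cohort in the two-column CSV dialect."""
    cfg = sd.SynthConfig(
        n_subjects=3, days=0.5, rng_seed=7,
        n_hypo_subjects=1, hypo_episodes_per_day=4.0,
        artifact_rate=0.04, outlier_rate=0.02, cgm_missing_pct=2.0,
    )
    out = tmp_path_factory.mktemp("cohort")
    sd.generate_cohort(cfg, out)
    return out
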