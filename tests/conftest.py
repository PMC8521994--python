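import numpy as np
import pandas as pd
import pytest

from aidlog import LogTable, StudyConfig


def make_log_frame(rows):
    """Build a canonical log DataFrame from (pid, side, ts, on_time_s, spl, snr) tuples."""
    df = pd.DataFrame(
        rows, columns=["participant_id", "side", "timestamp", "on_time_s", "spl_db", "snr_db"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["on_time_s"] = df["on_time_s"].astype(np.int64)
    return df


def minute_run(pid, side, start, n, on_time_start=60, spl=65.0, snr=5.0):
    """n consecutive minute logs with a healthy cumulative counter."""
    start = pd.Timestamp(start)
    return [
        (pid, side, start + pd.Timedelta(minutes=i), on_time_start + 60 * i, spl, snr)
        for i in range(n)
    ]


@pytest.fixture
def cfg():
    return StudyConfig()


@pytest.fixture
def tiny_table():
    """Two participants, one day, both sides, clean counters."""
    rows = (
        minute_run("P1", "left", "2019-06-03 08:00", 30)
        + minute_run("P1", "right", "2019-06-03 08:00", 25)
        + minute_run("P2", "left", "2019-06-03 09:00", 40)
        + minute_run("P2", "right", "2019-06-03 09:00", 40)
    )
    return LogTable(make_log_frame(rows), provenance="fixture")


@pytest.fixture(scope="session")
def default_cohort():
    """One modest default-parameter cohort shared by read-only tests."""
    from aidlog import simulate_cohort

    return simulate_cohort(n_participants=15, n_days=8, seed=42)


@pytest.fixture(scope="session")
def regime_fits():
    """Association-model fits on three default 40x12 cohorts (shared; slow)."""
    from aidlog import (
        daily_acoustics,
        daily_usage,
        filter_day_window,
        fit_usage_lmm,
        prepare_model_frame,
        remove_acoustic_outliers,
        simulate_cohort,
    )

    cfg = StudyConfig()
    results = []
    for seed in (3, 17, 41):
        table, _ = simulate_cohort(n_participants=40, n_days=12, seed=seed)
        table, _ = filter_day_window(table, cfg)
        du = daily_usage(table, cfg)
        acoustics = daily_acoustics(table, cfg)
        acoustics, _ = remove_acoustic_outliers(acoustics, cfg)
        frame = prepare_model_frame(du, acoustics)
        results.append(fit_usage_lmm(frame, cfg))
    return results
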