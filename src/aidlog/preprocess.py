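"""Inclusion filters applied before estimation and modelling.

Order in the pipeline driver is fixed: day-window filter first, then the
minimum-days participant filter; the day-level acoustic outlier filter
runs later, on daily summaries, just before association modelling.
All filters are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import LogTable

logger = logging.getLogger(__name__)

ACOUSTIC_SUMMARY_COLUMNS = ["spl_leq_db", "spl_sd_db", "snr_median_db"]


@dataclass
class FilterReport:
    """Before/after bookkeeping for one filter application."""

    name: str
    rows_before: int
    rows_after: int
    details: dict = field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return self.rows_before - self.rows_after


def filter_day_window(table: LogTable, cfg: StudyConfig) -> tuple[LogTable, FilterReport]:
    """Keep records whose wall-clock time lies in the half-open analysis window.

    Defaults to [06:00, 24:00): a record at 06:00 is kept, one at 05:59
    or at midnight is dropped (night logs are typically devices left on).
    """
    df = table.data
    hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
    keep = (hours >= cfg.day_window_start_hour) & (hours < cfg.day_window_end_hour)
    out = df.loc[keep].reset_index(drop=True)
    report = FilterReport("day_window", len(df), len(out))
    return LogTable(out, provenance=table.provenance, tz_label=table.tz_label), report


def filter_min_days(table: LogTable, cfg: StudyConfig) -> tuple[LogTable, FilterReport]:
    """Drop participants with fewer than the minimum distinct logging dates.

    Dates are counted across both sides; a participant is removed
    entirely, both streams included.
    """
    df = table.data
    if df.empty:
        return table, FilterReport("min_days", 0, 0)
    days = df.groupby("participant_id")["timestamp"].apply(lambda s: s.dt.date.nunique())
    keep_pids = set(days.index[days >= cfg.min_days_per_participant])
    out = df.loc[df["participant_id"].isin(keep_pids)].reset_index(drop=True)
    excluded = sorted(set(days.index) - keep_pids)
    report = FilterReport(
        "min_days", len(df), len(out), details={"participants_excluded": excluded}
    )
    return LogTable(out, provenance=table.provenance, tz_label=table.tz_label), report


def select_dominant_side(daily: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day, keep the side with the highest daily total usage.

    Ties break deterministically to the left side.  Used by the
    clustering stage, which treats a day as a single usage pattern.
    """
    df = daily.copy()
    # left sorts before right, so keep="first" after a stable sort on
    # (-usage, side) implements max-with-left-tie-break.
    df = df.sort_values(
        ["participant_id", "date", "t_remote_h", "side"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = df.drop_duplicates(subset=["participant_id", "date"], keep="first")
    return out.sort_values(["participant_id", "date"]).reset_index(drop=True)


def remove_acoustic_outliers(
    daily_acoustics: pd.DataFrame, cfg: StudyConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop days with extreme acoustic summaries at pooled quantiles.

    A day is removed when any of its three summaries (SPL Leq, SPLSD,
    median SNR) lies strictly below the pooled lower quantile or strictly
    above the pooled upper quantile of that summary (linear-interpolation
    quantiles, pooled across participants).  With fewer than 10 pooled
    days the filter is a no-op (warned).
    """
    df = daily_acoustics
    if len(df) < 10:
        logger.warning("remove_acoustic_outliers: fewer than 10 days pooled; skipping")
        return df.reset_index(drop=True), FilterReport("acoustic_outliers", len(df), len(df))
    lo_q, hi_q = cfg.outlier_quantiles
    bad = np.zeros(len(df), dtype=bool)
    per_column: dict[str, int] = {}
    for col in ACOUSTIC_SUMMARY_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        lo, hi = np.quantile(vals, [lo_q, hi_q])
        col_bad = (vals < lo) | (vals > hi)
        per_column[col] = int(col_bad.sum())
        bad |= col_bad
    out = df.loc[~bad].reset_index(drop=True)
    report = FilterReport(
        "acoustic_outliers",
        len(df),
        len(out),
        details={"days_removed": int(bad.sum()), "per_column": per_column},
    )
    return out, report
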