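"""Reading, writing and validating minute-resolution device log tables.

A log table holds one row per minute during which a hearing aid was worn
*and* connected to the relaying smartphone: participant id, device side,
local wall-clock timestamp (minute resolution), the cumulative on-time
counter maintained inside the device (seconds since last reset), and the
per-minute ambient SPL and SNR estimated by the device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["participant_id", "side", "timestamp", "on_time_s", "spl_db", "snr_db"]
KEY_COLUMNS = ["participant_id", "side", "timestamp"]
SIDES = ("left", "right")

#: Plausibility bounds for per-minute acoustics, dB.
SPL_RANGE = (0.0, 140.0)
SNR_RANGE = (-20.0, 30.0)

#: Canonical timestamp format: ISO-8601 local wall-clock at minute resolution.
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


@dataclass
class LogTable:
    """An ordered, validated collection of minute log records.

    ``data`` is a DataFrame with the six canonical columns, sorted by
    (participant_id, side, timestamp) and free of duplicate keys.
    Timestamps are naive local wall-clock instants; ``tz_label`` is a
    declarative label only (no timezone arithmetic is ever performed).
    """

    data: pd.DataFrame
    provenance: str = "synthetic"
    tz_label: str = "local"

    def __len__(self) -> int:
        return len(self.data)

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"log table is missing required columns: {missing}")


@dataclass
class ValidationReport:
    """Pure report of log-table anomalies; the table itself is untouched."""

    n_rows: int
    counter_resets: pd.DataFrame
    out_of_range: pd.DataFrame
    n_duplicate_keys: int

    @property
    def n_counter_resets(self) -> int:
        return len(self.counter_resets)

    @property
    def n_out_of_range(self) -> int:
        return len(self.out_of_range)

    @property
    def ok(self) -> bool:
        return (
            self.n_counter_resets == 0
            and self.n_out_of_range == 0
            and self.n_duplicate_keys == 0
        )


def _normalize(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Coerce types, truncate timestamps to the minute, drop bad rows.

    Returns the cleaned frame plus drop counts per reason.
    """
    counts = {"unparseable": 0, "duplicate_key": 0}
    out = df.loc[:, LOG_COLUMNS].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["side"] = out["side"].astype(str).str.lower()
    out["timestamp"] = pd.to_datetime(
        out["timestamp"], errors="coerce", format="mixed"
    ).dt.floor("min")
    for col in ("on_time_s", "spl_db", "snr_db"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = (
        out["timestamp"].isna()
        | out[["on_time_s", "spl_db", "snr_db"]].isna().any(axis=1)
        | ~out["side"].isin(SIDES)
    )
    counts["unparseable"] = int(bad.sum())
    out = out.loc[~bad]
    dup = out.duplicated(subset=KEY_COLUMNS, keep="first")
    counts["duplicate_key"] = int(dup.sum())
    out = out.loc[~dup]
    out = out.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    out["on_time_s"] = out["on_time_s"].astype(np.int64)
    return out, counts


def read_log_csv(path: str | Path, tz_label: str = "local") -> LogTable:
    """Read a canonical minute-log CSV into a validated, sorted LogTable.

    Rows failing type coercion and duplicate (participant, side, timestamp)
    keys are dropped, with counts logged at INFO level.  A missing required
    column is a hard error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse log CSV {path}: {exc}") from exc
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log CSV {path} is missing required column(s): {missing}")
    clean, counts = _normalize(df)
    if counts["unparseable"] or counts["duplicate_key"]:
        logger.info(
            "read_log_csv(%s): dropped %d unparseable and %d duplicate-key rows",
            path,
            counts["unparseable"],
            counts["duplicate_key"],
        )
    return LogTable(data=clean, provenance=str(path), tz_label=tz_label)


def write_log_csv(table: LogTable, path: str | Path) -> None:
    """Write a LogTable in the canonical CSV dialect (round-trip safe)."""
    out = table.data.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)


def validate_log_table(table: LogTable) -> ValidationReport:
    """Report counter resets, out-of-range acoustics and duplicate keys."""
    df = table.data
    diffs = df.groupby(["participant_id", "side"], sort=False)["on_time_s"].diff()
    resets = df.loc[diffs < 0, KEY_COLUMNS + ["on_time_s"]]
    bad_spl = ~df["spl_db"].between(*SPL_RANGE)
    bad_snr = ~df["snr_db"].between(*SNR_RANGE)
    out_of_range = df.loc[bad_spl | bad_snr, KEY_COLUMNS + ["spl_db", "snr_db"]]
    n_dup = int(df.duplicated(subset=KEY_COLUMNS).sum())
    return ValidationReport(
        n_rows=len(df),
        counter_resets=resets.reset_index(drop=True),
        out_of_range=out_of_range.reset_index(drop=True),
        n_duplicate_keys=n_dup,
    )


def split_participant_days(table: LogTable):
    """Partition a table into (participant_id, date, side, slice) groups.

    A day is the local calendar date of the timestamp.  Every input row
    appears in exactly one slice; within-slice order is preserved.
    """
    df = table.data
    if df.empty:
        return []
    dates = df["timestamp"].dt.date
    groups = []
    for (pid, date, side), chunk in df.groupby(
        ["participant_id", dates, "side"], sort=True
    ):
        groups.append((pid, date, side, chunk))
    return groups
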