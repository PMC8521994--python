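"""The two daily usage estimators and connectivity summaries.

Daily hearing-aid usage is estimated two ways.  T_remote counts unique
minute-resolution timestamps in the analysis window - each log minute
represents 60 s of worn *and* connected time, so T_remote undercounts
whenever the phone link drops.  T_intrinsic differences the device's
cumulative on-time counter between consecutive logs, which bridges
connectivity gaps: it recovers true on-time between the first and last
log of the day.  Their relative difference

    dT_rel = (T_intrinsic - T_remote) / T_intrinsic

is the fraction of worn time lost from the remote logs, and
100 * (1 - dT_rel) is the day's smartphone connectivity percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import LogTable


@dataclass(frozen=True)
class TIntrinsicResult:
    """Accumulated-counter estimate for one device-day."""

    seconds: float
    n_resets: int = 0
    insufficient_records: bool = False


def _window_slice(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
    keep = (hours >= cfg.day_window_start_hour) & (hours < cfg.day_window_end_hour)
    return df.loc[keep]


def t_remote(logs: pd.DataFrame, cfg: StudyConfig | None = None) -> int:
    """Timestamp-counting estimator: unique log minutes in the window.

    Each unique minute-resolution timestamp counts as one minute (60 s)
    of connected on-time; duplicate or sub-minute stamps collapse.
    """
    cfg = cfg or StudyConfig()
    if logs.empty:
        return 0
    sliced = _window_slice(logs, cfg)
    return int(sliced["timestamp"].nunique())


def t_intrinsic(logs: pd.DataFrame, cfg: StudyConfig | None = None) -> TIntrinsicResult:
    """Counter-differencing estimator: sum of consecutive on-time increments.

    Negative differences mark counter resets (clinical visits); they
    contribute zero and are flagged rather than spliced.  Fewer than two
    records in the window yields 0 s with an ``insufficient_records``
    flag.
    """
    cfg = cfg or StudyConfig()
    sliced = _window_slice(logs, cfg).sort_values("timestamp")
    if len(sliced) < 2:
        return TIntrinsicResult(0.0, insufficient_records=True)
    diffs = np.diff(sliced["on_time_s"].to_numpy(dtype=float))
    n_resets = int(np.sum(diffs < 0))
    seconds = float(diffs[diffs > 0].sum())
    return TIntrinsicResult(seconds, n_resets=n_resets)


DAILY_USAGE_COLUMNS = [
    "participant_id",
    "date",
    "side",
    "t_remote_h",
    "t_intrinsic_h",
    "delta_abs_h",
    "delta_rel",
    "connectivity_pct",
    "n_counter_resets",
]


def daily_usage(table: LogTable, cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Both estimators per (participant, date, side).

    ``delta_abs_h`` is the magnitude of the remote-log underestimate,
    T_intrinsic - T_remote in hours.  ``delta_rel`` is clamped to [0, 1]
    (timestamp quantization can push T_remote marginally above
    T_intrinsic) and is null when T_intrinsic is zero.
    """
    cfg = cfg or StudyConfig()
    records = []
    df = table.data
    if df.empty:
        return pd.DataFrame(columns=DAILY_USAGE_COLUMNS)
    for (pid, date, side), chunk in df.groupby(
        ["participant_id", df["timestamp"].dt.date, "side"], sort=True
    ):
        tr_min = t_remote(chunk, cfg)
        ti = t_intrinsic(chunk, cfg)
        tr_h = tr_min / 60.0
        ti_h = ti.seconds / 3600.0
        delta_abs = ti_h - tr_h
        if ti_h > 0:
            delta_rel = float(np.clip(delta_abs / ti_h, 0.0, 1.0))
            conn = 100.0 * (1.0 - delta_rel)
        else:
            delta_rel = np.nan
            conn = np.nan
        records.append(
            {
                "participant_id": pid,
                "date": date,
                "side": side,
                "t_remote_h": tr_h,
                "t_intrinsic_h": ti_h,
                "delta_abs_h": delta_abs,
                "delta_rel": delta_rel,
                "connectivity_pct": conn,
                "n_counter_resets": ti.n_resets,
            }
        )
    return pd.DataFrame(records, columns=DAILY_USAGE_COLUMNS)


def hourly_vector(logs: pd.DataFrame, cfg: StudyConfig | None = None) -> np.ndarray:
    """Minutes of usage per analysis-window hour for one device-day.

    Returns an 18-element vector (hours 06..23 at defaults); entry i is
    the count of unique log minutes in that hour, in [0, 60].
    """
    cfg = cfg or StudyConfig()
    n_hours = cfg.n_window_hours
    vec = np.zeros(n_hours, dtype=float)
    if logs.empty:
        return vec
    sliced = _window_slice(logs, cfg).drop_duplicates(subset="timestamp")
    hours = sliced["timestamp"].dt.hour.to_numpy() - cfg.day_window_start_hour
    counts = np.bincount(hours, minlength=n_hours)
    vec[:] = counts[:n_hours]
    return vec


def hourly_vectors(
    table: LogTable, selection: pd.DataFrame, cfg: StudyConfig | None = None
) -> pd.DataFrame:
    """Hourly usage vectors for the selected (dominant-side) days.

    ``selection`` carries one row per (participant_id, date, side) -
    typically the output of ``preprocess.select_dominant_side``.  Returns
    a frame indexed by (participant_id, date) with one column per window
    hour, named ``h06`` .. ``h23`` at defaults.
    """
    cfg = cfg or StudyConfig()
    df = table.data
    cols = [f"h{h:02d}" for h in range(cfg.day_window_start_hour, cfg.day_window_end_hour)]
    keys = selection[["participant_id", "date", "side"]]
    grouped = {
        (pid, date, side): chunk
        for (pid, date, side), chunk in df.groupby(
            ["participant_id", df["timestamp"].dt.date, "side"], sort=False
        )
    }
    rows, index = [], []
    for pid, date, side in keys.itertuples(index=False):
        chunk = grouped.get((pid, date, side))
        vec = hourly_vector(chunk, cfg) if chunk is not None else np.zeros(len(cols))
        rows.append(vec)
        index.append((pid, date))
    out = pd.DataFrame(rows, columns=cols)
    out.index = pd.MultiIndex.from_tuples(index, names=["participant_id", "date"])
    return out


@dataclass(frozen=True)
class ConnectivitySummary:
    """Pooled and participant-aggregated connectivity medians."""

    pooled_median_delta_abs_h: float
    pooled_median_delta_rel: float
    grand_median_participant_mean_delta_abs_h: float
    n_days: int
    n_participants: int


def pooled_connectivity_summary(daily: pd.DataFrame) -> ConnectivitySummary:
    """Median underestimation pooled over days and via two-stage aggregation.

    The pooled median is over all device-days; the grand median first
    averages within participant, then takes the median across
    participants.  Values are magnitudes of the remote-log underestimate.
    Days with undefined delta_rel (zero intrinsic on-time) are excluded
    from the delta_rel median.
    """
    if daily.empty:
        raise ValueError("no days available for connectivity summary")
    valid_rel = daily["delta_rel"].dropna()
    per_participant = daily.groupby("participant_id")["delta_abs_h"].mean()
    return ConnectivitySummary(
        pooled_median_delta_abs_h=float(daily["delta_abs_h"].median()),
        pooled_median_delta_rel=float(valid_rel.median()) if len(valid_rel) else np.nan,
        grand_median_participant_mean_delta_abs_h=float(per_participant.median()),
        n_days=len(daily),
        n_participants=daily["participant_id"].nunique(),
    )


def connectivity_by_bin(daily: pd.DataFrame, cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Per-participant mean dT_rel stratified by intrinsic on-time bins.

    Bins partition (0, window-length] hours, right-closed, with the
    configured width.  Returns one row per populated bin with the median
    and IQR of per-participant means, mirroring the "is data loss a
    constant or a ratio" diagnostic: flat medians across bins indicate a
    constant per-minute loss rate.
    """
    cfg = cfg or StudyConfig()
    width = cfg.on_time_bin_width_h
    total_h = cfg.n_window_hours
    edges = np.arange(0.0, total_h + width, width)
    edges = edges[edges <= total_h + 1e-9]
    if edges[-1] < total_h:
        edges = np.append(edges, total_h)
    df = daily.dropna(subset=["delta_rel"]).copy()
    df = df[df["t_intrinsic_h"] > 0]
    df["on_time_bin"] = pd.cut(df["t_intrinsic_h"], bins=edges, right=True)
    per_part = (
        df.groupby(["on_time_bin", "participant_id"], observed=True)["delta_rel"]
        .mean()
        .rename("mean_delta_rel")
        .reset_index()
    )
    out = (
        per_part.groupby("on_time_bin", observed=True)["mean_delta_rel"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n_participants="count",
        )
        .reset_index()
    )
    out["bin_label"] = out["on_time_bin"].astype(str)
    return out


def connectivity_by_cluster(daily: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Mean and SD of connectivity percentage per usage-pattern cluster.

    ``assignments`` maps (participant_id, date) to a cluster label for
    the dominant-side days; ``daily`` must contain those days.  Keys in
    the assignment with no matching day are an error.
    """
    df = daily.set_index(["participant_id", "date"])
    if df.index.has_duplicates:
        raise ValueError(
            "daily must hold one side per participant-day (use select_dominant_side)"
        )
    orphans = [k for k in assignments.index if k not in df.index]
    if orphans:
        raise KeyError(f"cluster assignments without matching days: {orphans[:5]}")
    joined = df.loc[assignments.index].copy()
    joined["cluster"] = assignments.to_numpy()
    out = (
        joined.groupby("cluster")["connectivity_pct"]
        .agg(mean_connectivity_pct="mean", sd_connectivity_pct="std", n_days="count")
        .reset_index()
    )
    return out
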