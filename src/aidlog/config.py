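"""Study-level configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StudyConfig:
    """Fixed analysis constants.

    The analysis window, inclusion rule and outlier rule mirror the
    conventions of remote hearing-aid datalogging studies: minute logs
    between 06:00 and midnight (night logs are dominated by devices left
    on accidentally), participants with at least two days of logging,
    and day-level acoustic summaries trimmed at the pooled 1%/99%
    quantiles before association modelling.

    Attributes
    ----------
    day_window_start_hour, day_window_end_hour:
        Half-open wall-clock window [start, end) in hours; defaults give
        [06:00, 24:00), i.e. the 18 analysis hours 06..23.
    min_days_per_participant:
        Minimum number of distinct calendar dates (either side) for a
        participant to be retained.
    outlier_quantiles:
        Pooled lower/upper quantiles used to drop extreme acoustic days.
    kmeans_k_max, kmeans_restarts:
        Elbow search range and number of seeded k-means restarts per k.
    rng_seed:
        Seed for any stochastic step driven by the configuration.
    on_time_bin_width_h:
        Width of the on-time strata used for connectivity-by-bin summaries.
    min_minutes_per_day:
        Minimum logged minutes for a day to enter the acoustic stage.
    """

    day_window_start_hour: int = 6
    day_window_end_hour: int = 24
    min_days_per_participant: int = 2
    outlier_quantiles: tuple[float, float] = (0.01, 0.99)
    kmeans_k_max: int = 10
    kmeans_restarts: int = 25
    rng_seed: int = 0
    on_time_bin_width_h: float = 2.0
    min_minutes_per_day: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.day_window_start_hour < self.day_window_end_hour <= 24:
            raise ValueError(
                "day window must satisfy 0 <= start < end <= 24, got "
                f"[{self.day_window_start_hour}, {self.day_window_end_hour})"
            )
        lo, hi = self.outlier_quantiles
        if not 0 <= lo < hi <= 1:
            raise ValueError(f"outlier quantiles must satisfy 0 <= lo < hi <= 1, got {lo}, {hi}")
        if self.min_days_per_participant < 1:
            raise ValueError("min_days_per_participant must be >= 1")
        if self.kmeans_k_max < 1 or self.kmeans_restarts < 1:
            raise ValueError("kmeans_k_max and kmeans_restarts must be >= 1")
        if self.on_time_bin_width_h <= 0:
            raise ValueError("on_time_bin_width_h must be positive")

    @property
    def n_window_hours(self) -> int:
        return self.day_window_end_hour - self.day_window_start_hour
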