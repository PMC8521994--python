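"""Synthetic minute-log cohorts with known ground truth.

The generator emulates the data-producing process of smartphone-relayed
hearing-aid logs: a wearer puts the aids on according to one of four
archetypal daily patterns, the devices accumulate on-time every worn
minute, but a minute log is only *emitted* when the Bluetooth link to
the phone is up.  Ambient acoustics follow a three-state context chain
(quiet / speech-in-noise / loud-diverse) whose state weights tilt toward
noisier contexts on longer-wear days, so usage-environment associations
arise mechanistically rather than being painted onto the outputs.

Every stochastic step is driven by a single numpy Generator, so a cohort
is bitwise reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LogTable

MINUTES_PER_DAY = 1440

ARCHETYPE_NAMES = ("morning", "afternoon_evening", "sparse", "all_day")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Template for one archetypal daily wear pattern.

    Templated archetypes carry fixed (start, end) sessions in minutes of
    day, jittered per day by a uniform offset; the ``sparse`` archetype
    instead scatters a random number of short epochs inside its window.
    Sessions are clamped to the 06:00-24:00 day and never overlap.
    """

    name: str
    sessions: tuple[tuple[int, int], ...] = ()
    jitter_min: int = 45
    n_epochs: tuple[int, int] = (4, 6)
    epoch_duration_min: tuple[int, int] = (20, 60)
    epoch_window: tuple[int, int] = (7 * 60, 23 * 60)


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The four default daily wear archetypes.

    morning 06:30-14:30, afternoon_evening 12:00-23:00, all_day
    07:00-22:30, each with +/-45 min edge jitter; sparse scatters 4-6
    epochs of 20-60 min inside 07:00-23:00.
    """
    return {
        "morning": ArchetypeSpec("morning", sessions=((390, 870),)),
        "afternoon_evening": ArchetypeSpec("afternoon_evening", sessions=((720, 1380),)),
        "sparse": ArchetypeSpec("sparse"),
        "all_day": ArchetypeSpec("all_day", sessions=((420, 1350),)),
    }


@dataclass(frozen=True)
class ConnectivityModel:
    """Per-minute smartphone-link model applied to worn minutes.

    ``bernoulli`` drops each worn minute independently; the default
    ``two_state_markov`` produces bursty outages with geometric run
    lengths (mean ``mean_dropout_burst_min``) at the same stationary
    availability.  ``availability_day_sd`` lets the cohort simulator
    vary the availability from device-day to device-day (phone left in
    another room, Bluetooth toggled ...), reproducing the wide between-
    day spread of data loss seen in remote logs; it does not affect a
    single ``apply_connectivity`` call, whose stationary availability is
    exactly ``availability``.
    """

    kind: str = "two_state_markov"
    availability: float = 0.85
    mean_dropout_burst_min: float = 10.0
    availability_day_sd: float = 0.18

    def __post_init__(self) -> None:
        if self.kind not in ("bernoulli", "two_state_markov"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        if not 0 < self.availability <= 1:
            raise ValueError("availability must be in (0, 1]")
        if self.mean_dropout_burst_min < 1:
            raise ValueError("mean_dropout_burst_min must be >= 1")
        if self.availability_day_sd < 0:
            raise ValueError("availability_day_sd must be >= 0")

    def day_availability(self, rng: np.random.Generator) -> float:
        """Draw one device-day's availability (median = ``availability``)."""
        if self.availability_day_sd == 0:
            return self.availability
        a = rng.normal(self.availability, self.availability_day_sd)
        return float(np.clip(a, 0.05, 1.0))


@dataclass(frozen=True)
class AcousticModel:
    """Three-state ambient-context chain with per-state SPL/SNR laws.

    Per-minute SNR is a shifted log-normal (shift -2 dB) per context
    state, giving the right-skewed, almost-always-positive SNR
    distribution seen in device logs, with a small negative tail.
    Per-minute SPL combines a state level, a day-level intensity offset,
    and within-state noise scaled by a day-level *diversity* factor; the
    within-state noise is negatively skewed (bounded above, long lower
    tail), as minute-level SPL distributions are, which keeps the
    energetic day average (Leq) from being dominated by Gaussian upper
    tails.  Intensity and diversity therefore vary semi-independently
    across days, as in real sound environments.

    Usage coupling is mechanistic and threefold, all monotone in the
    day's planned wear: the quiet-context weight falls (more
    speech-in-noise and loud minutes, hence lower SNR and higher Leq),
    the day intensity offset rises, and the day diversity factor rises.
    ``coupling_strength = 0`` severs all three links (null generator).
    """

    state_names: tuple[str, ...] = ("quiet", "speech_in_noise", "loud_diverse")
    spl_mean_db: tuple[float, ...] = (56.0, 64.0, 69.5)
    spl_sd_db: tuple[float, ...] = (8.5, 9.5, 11.0)
    snr_log_mu: tuple[float, ...] = (2.08, 1.30, 1.45)
    snr_log_sigma: tuple[float, ...] = (0.50, 0.55, 0.60)
    snr_shift_db: float = -2.0
    spl_skew: float = 0.6
    day_level_sd: float = 4.0
    day_level_slope_per_h: float = 0.17
    diversity_sd: float = 0.12
    diversity_slope_per_h: float = 0.010
    persistence: float = 0.97
    base_quiet_weight: float = 0.72
    quiet_weight_slope_per_h: float = 0.022
    min_quiet_weight: float = 0.20
    noisy_split: float = 0.70
    coupling_strength: float = 1.0
    reference_wear_h: float = 9.0

    def __post_init__(self) -> None:
        n = len(self.state_names)
        for tup in (self.spl_mean_db, self.spl_sd_db, self.snr_log_mu, self.snr_log_sigma):
            if len(tup) != n:
                raise ValueError("per-state parameter tuples must match state_names")
        if any(sd < 0 for sd in self.spl_sd_db):
            raise ValueError("SPL standard deviations must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if not 0 < self.noisy_split < 1:
            raise ValueError("noisy_split must be in (0, 1)")

    def state_weights(self, planned_wear_min: float) -> np.ndarray:
        """Stationary state distribution for a day with the given planned wear.

        Monotone non-increasing in quiet weight as planned wear grows.
        """
        hours = planned_wear_min / 60.0
        quiet = self.base_quiet_weight - self.coupling_strength * self.quiet_weight_slope_per_h * hours
        quiet = float(np.clip(quiet, self.min_quiet_weight, 0.95))
        rest = 1.0 - quiet
        pi = np.array([quiet, rest * self.noisy_split, rest * (1.0 - self.noisy_split)])
        if np.any(pi <= 0):
            raise ValueError("degenerate context chain: some state weight is non-positive")
        return pi

    def transition_matrix(self, planned_wear_min: float) -> np.ndarray:
        """Sticky chain P = rho*I + (1-rho)*1 pi^T with stationary pi."""
        pi = self.state_weights(planned_wear_min)
        n = len(pi)
        return self.persistence * np.eye(n) + (1 - self.persistence) * np.tile(pi, (n, 1))


def _markov_states(n: int, pi: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate n steps of the sticky chain (vectorized forward fill)."""
    fresh = rng.choice(len(pi), size=n, p=pi)
    redraw = rng.random(n) >= rho
    redraw[0] = True
    seg = np.maximum.accumulate(np.where(redraw, np.arange(n), 0))
    return fresh[seg]


def generate_wear_mask(spec: ArchetypeSpec, rng: np.random.Generator) -> np.ndarray:
    """One day's wear mask: 1440 booleans, true during jittered sessions."""
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    if spec.name == "sparse" or not spec.sessions:
        lo, hi = spec.epoch_window
        n_epochs = int(rng.integers(spec.n_epochs[0], spec.n_epochs[1] + 1))
        for _ in range(n_epochs):
            dur = int(rng.integers(spec.epoch_duration_min[0], spec.epoch_duration_min[1] + 1))
            for _attempt in range(200):
                start = int(rng.integers(lo, hi - dur + 1))
                if not mask[start : start + dur].any():
                    mask[start : start + dur] = True
                    break
        return mask
    prev_end = 6 * 60
    for start, end in spec.sessions:
        if spec.jitter_min > 0:
            start = start + int(rng.integers(-spec.jitter_min, spec.jitter_min + 1))
            end = end + int(rng.integers(-spec.jitter_min, spec.jitter_min + 1))
        start = max(start, prev_end, 6 * 60)
        end = min(end, MINUTES_PER_DAY)
        if end > start:
            mask[start:end] = True
            prev_end = end
    return mask


def generate_acoustics(
    mask: np.ndarray,
    model: AcousticModel,
    planned_wear_min: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-worn-minute (spl_db, snr_db, state index) for one day.

    The context chain runs over the worn minutes only (contexts carry
    across short off gaps, which is immaterial at minute resolution).
    """
    n = int(np.count_nonzero(mask))
    if n < 1:
        raise ValueError("wear mask has no worn minutes")
    pi = model.state_weights(planned_wear_min)
    states = _markov_states(n, pi, model.persistence, rng)
    hours = planned_wear_min / 60.0
    excess_h = model.coupling_strength * (hours - model.reference_wear_h)
    day_level = model.day_level_slope_per_h * excess_h
    if model.day_level_sd > 0:
        day_level += rng.normal(0.0, model.day_level_sd)
    diversity = 1.0 + model.diversity_slope_per_h * excess_h
    if model.diversity_sd > 0:
        diversity += rng.normal(0.0, model.diversity_sd)
    diversity = max(diversity, 0.0)
    noise = _neg_skew_noise(n, model.spl_skew, rng)
    spl = (
        np.asarray(model.spl_mean_db)[states]
        + day_level
        + diversity * np.asarray(model.spl_sd_db)[states] * noise
    )
    snr = model.snr_shift_db + rng.lognormal(
        np.asarray(model.snr_log_mu)[states], np.asarray(model.snr_log_sigma)[states]
    )
    # devices report within a bounded measurement range
    from .io import SNR_RANGE, SPL_RANGE

    np.clip(spl, SPL_RANGE[0], SPL_RANGE[1], out=spl)
    np.clip(snr, SNR_RANGE[0], SNR_RANGE[1], out=snr)
    return spl, snr, states


def _neg_skew_noise(n: int, skew: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized left-skewed noise (mean 0, SD 1, bounded above).

    Built as the negated, standardized log-normal(0, skew); ``skew = 0``
    degenerates to exactly zero noise (useful for worked examples).
    """
    if skew <= 0:
        return np.zeros(n)
    x = rng.lognormal(0.0, skew, size=n)
    mean = np.exp(skew**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(skew**2))
    return (mean - x) / sd


def apply_connectivity(
    mask: np.ndarray, model: ConnectivityModel, rng: np.random.Generator
) -> np.ndarray:
    """Observed-minute mask: subset of the wear mask surviving the phone link."""
    worn = np.flatnonzero(mask)
    n = worn.size
    observed = mask.copy()
    if n == 0:
        return observed
    if model.kind == "bernoulli":
        keep = rng.random(n) < model.availability
    else:
        keep = _markov_connected(n, model, rng)
    observed[worn[~keep]] = False
    return observed


def _markov_connected(n: int, model: ConnectivityModel, rng: np.random.Generator) -> np.ndarray:
    """Two-state (connected/disconnected) chain over n worn minutes."""
    a = model.availability
    if a >= 1.0:
        return np.ones(n, dtype=bool)
    p_reconnect = 1.0 / model.mean_dropout_burst_min
    p_drop = p_reconnect * (1 - a) / a
    p_drop = min(p_drop, 1.0)
    u = rng.random(n)
    connected = np.empty(n, dtype=bool)
    connected[0] = u[0] < a
    for i in range(1, n):
        if connected[i - 1]:
            connected[i] = u[i] >= p_drop
        else:
            connected[i] = u[i] < p_reconnect
    return connected


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generator settings (YAML-mappable)."""

    n_participants: int = 50
    n_days: int = 10
    archetype_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    stickiness: float = 0.55
    seed: int = 0
    start_date: str = "2019-06-03"
    night_contamination_prob: float = 0.0
    interruption_prob: float = 0.35
    interruption_min: tuple[int, int] = (30, 240)
    connectivity: ConnectivityModel = field(default_factory=ConnectivityModel)
    acoustics: AcousticModel = field(default_factory=AcousticModel)

    def __post_init__(self) -> None:
        mix = np.asarray(self.archetype_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_mix must be 4 non-negative weights summing to 1")
        if not 0 <= self.stickiness <= 1:
            raise ValueError("stickiness must be in [0, 1]")


def _remove_worn_chunk(
    mask: np.ndarray, duration_range: tuple[int, int], rng: np.random.Generator
) -> None:
    """Clear one contiguous run of worn minutes in place (wear interruption)."""
    worn = np.flatnonzero(mask)
    if worn.size <= 60:
        return
    dur = int(rng.integers(duration_range[0], duration_range[1] + 1))
    dur = min(dur, worn.size - 30)
    start = int(rng.integers(0, worn.size - dur + 1))
    mask[worn[start : start + dur]] = False


TRUTH_COLUMNS = [
    "participant_id",
    "date",
    "side",
    "archetype",
    "true_on_time_min",
    "realized_connectivity",
    "occ_quiet",
    "occ_speech_in_noise",
    "occ_loud_diverse",
]


def simulate_cohort(
    n_participants: int = 50,
    n_days: int = 10,
    archetype_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    conn: ConnectivityModel | None = None,
    ac: AcousticModel | None = None,
    seed: int = 0,
    start_date: str = "2019-06-03",
    stickiness: float = 0.55,
    archetypes: dict[str, ArchetypeSpec] | None = None,
    night_contamination_prob: float = 0.0,
    interruption_prob: float = 0.35,
    interruption_min: tuple[int, int] = (30, 240),
) -> tuple[LogTable, pd.DataFrame]:
    """Simulate a cohort of bilateral minute logs plus ground truth.

    Each participant draws an archetype preference from ``archetype_mix``
    and, each day, follows it with probability ``stickiness`` (else a
    fresh draw from the mix), giving realistic between-participant usage
    heterogeneity while keeping the marginal archetype frequencies equal
    to the mix.  With probability ``interruption_prob`` a day loses one
    contiguous worn chunk (aids set aside mid-day); the interruption is
    applied *after* the day's acoustic context is planned, so it adds
    usage variability that the ambient environment does not explain.
    Both ears share the day's wear mask and acoustic environment; each
    side has independent connectivity.  The cumulative on-time counter
    advances 60 s for *every* worn minute, observed or not, so intrinsic
    on-time survives connectivity gaps.

    With ``night_contamination_prob`` > 0, a day may additionally log a
    00:00-06:00 block (aids left on overnight), for exercising the
    day-window filter.

    Returns (LogTable, truth frame with one row per participant-day-side).
    """
    conn = conn or ConnectivityModel()
    ac = ac or AcousticModel()
    specs = archetypes or default_archetypes()
    mix = np.asarray(archetype_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("archetype_mix must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    day0 = pd.Timestamp(start_date)
    minutes_of_day = np.arange(MINUTES_PER_DAY)

    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for p in range(n_participants):
        pid = f"S{p + 1:03d}"
        preference = int(rng.choice(4, p=mix))
        counters = {"left": 0, "right": 0}
        for d in range(n_days):
            date = day0 + pd.Timedelta(days=d)
            arch_idx = preference if rng.random() < stickiness else int(rng.choice(4, p=mix))
            arch = ARCHETYPE_NAMES[arch_idx]
            mask = generate_wear_mask(specs[arch], rng)
            if night_contamination_prob > 0 and rng.random() < night_contamination_prob:
                mask[: 6 * 60] = True
            planned_context = int(mask.sum())
            if planned_context == 0:
                continue
            if interruption_prob > 0 and rng.random() < interruption_prob:
                _remove_worn_chunk(mask, interruption_min, rng)
            planned = int(mask.sum())
            if planned == 0:
                continue
            spl, snr, states = generate_acoustics(mask, ac, planned_context, rng)
            occ = np.bincount(states, minlength=3) / planned
            worn_idx = np.flatnonzero(mask)
            cum_on = np.cumsum(mask) * 60  # counter value at end of each minute
            timestamps = date + pd.to_timedelta(minutes_of_day[worn_idx], unit="m")
            for side in ("left", "right"):
                day_conn = replace(conn, availability=conn.day_availability(rng))
                observed = apply_connectivity(mask, day_conn, rng)
                obs_at_worn = observed[worn_idx]
                n_obs = int(obs_at_worn.sum())
                if n_obs > 0:
                    rows.append(
                        pd.DataFrame(
                            {
                                "participant_id": pid,
                                "side": side,
                                "timestamp": timestamps[obs_at_worn],
                                "on_time_s": counters[side] + cum_on[worn_idx][obs_at_worn],
                                "spl_db": spl[obs_at_worn],
                                "snr_db": snr[obs_at_worn],
                            }
                        )
                    )
                counters[side] += planned * 60
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "date": date.date(),
                        "side": side,
                        "archetype": arch,
                        "true_on_time_min": planned,
                        "realized_connectivity": n_obs / planned,
                        "occ_quiet": occ[0],
                        "occ_speech_in_noise": occ[1],
                        "occ_loud_diverse": occ[2],
                    }
                )
    if rows:
        data = pd.concat(rows, ignore_index=True)
        data = data.sort_values(["participant_id", "side", "timestamp"], kind="mergesort")
        data = data.reset_index(drop=True)
    else:
        data = pd.DataFrame(
            {
                "participant_id": pd.Series(dtype=str),
                "side": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns]"),
                "on_time_s": pd.Series(dtype=np.int64),
                "spl_db": pd.Series(dtype=float),
                "snr_db": pd.Series(dtype=float),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return LogTable(data=data, provenance="synthetic", tz_label="local"), truth


def simulate_from_config(cfg: SimConfig) -> tuple[LogTable, pd.DataFrame]:
    return simulate_cohort(
        n_participants=cfg.n_participants,
        n_days=cfg.n_days,
        archetype_mix=cfg.archetype_mix,
        conn=cfg.connectivity,
        ac=cfg.acoustics,
        seed=cfg.seed,
        start_date=cfg.start_date,
        stickiness=cfg.stickiness,
        night_contamination_prob=cfg.night_contamination_prob,
        interruption_prob=cfg.interruption_prob,
        interruption_min=cfg.interruption_min,
    )


def simulate_linear_response(
    acoustics: pd.DataFrame,
    beta: tuple[float, float, float],
    intercept: float = 8.0,
    participant_intercept_sd: float = 2.0,
    participant_slope_sd: tuple[float, float, float] = (0.3, 0.3, 0.3),
    residual_sd: float = 2.0,
    seed: int = 0,
) -> pd.Series:
    """Draw a daily-usage response from an explicit linear mixed model.

    Used for parameter-recovery checks of the association stage: given a
    frame of standardized day-level predictors (columns ``leq_z``,
    ``splsd_z``, ``snr_z`` and ``participant_id``), returns usage hours
    generated as intercept + X beta + participant intercept + participant
    slopes . X + Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    pids = acoustics["participant_id"].to_numpy()
    unique = np.unique(pids)
    u0 = dict(zip(unique, rng.normal(0, participant_intercept_sd, len(unique))))
    X = acoustics[["leq_z", "splsd_z", "snr_z"]].to_numpy()
    slopes = {
        pid: rng.normal(0, np.asarray(participant_slope_sd)) for pid in unique
    }
    y = intercept + X @ np.asarray(beta, dtype=float)
    y = y + np.array([u0[p] for p in pids])
    y = y + np.einsum("ij,ij->i", X, np.vstack([slopes[p] for p in pids]))
    y = y + rng.normal(0, residual_sd, len(pids))
    return pd.Series(y, index=acoustics.index, name="usage_h")
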