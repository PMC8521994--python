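# aidlog

Analytics for minute-resolution **remote hearing-aid datalogs** — the logs a
smartphone collects over Bluetooth from a connected hearing aid. Each log
minute carries the device's cumulative on-time counter plus two descriptors
of the ambient scene, the sound pressure level (SPL, dB) and the estimated
signal-to-noise ratio (SNR, dB). Such data promise ecologically valid
pictures of when and where people actually wear their aids, but a minute is
only logged while the phone link is up, so naive timestamp counting
undercounts wear time. `aidlog` is for hearing researchers and audiology
data scientists who need to work with this kind of log.

The package implements:

- **Dual usage estimators** per participant-day-side: `T_remote` (count of
  unique minute stamps; 1 stamp = 60 s of worn-and-connected time) and
  `T_intrinsic = Σₙ (tₙ − tₙ₋₁)` over the device's cumulative on-time
  counter, which bridges connectivity gaps. Their relative difference
  `ΔT_rel = (T_intrinsic − T_remote) / T_intrinsic` measures data loss, and
  `100·(1 − ΔT_rel)` is the day's smartphone connectivity percentage.
- **Daily-pattern clustering**: K-means on 18-vectors of minutes used per
  hour (06:00–24:00), with an automated elbow rule (max chord distance on
  the normalized within-SS curve) and the silhouette coefficient
  `SC = (b − a)/max(a, b)`.
- **Acoustic association modelling**: day-level SPL L_eq (energetic mean),
  SPL standard deviation (SPLSD) and median SNR as predictors of daily
  usage in a linear mixed model with crossed random intercepts
  (participant, day of week, laterality, participant-day) and random slopes,
  plus likelihood-ratio tests, VIFs and Nakagawa marginal/conditional R².
- **A calibrated synthetic cohort generator** (four wear archetypes, bursty
  Bluetooth dropout, three-state acoustic context chain with mechanistic
  usage–environment coupling) so every stage is testable with known ground
  truth. Real cohorts of this kind are ethically restricted from sharing.

## Worked example

```python
from aidlog import (StudyConfig, simulate_cohort, filter_day_window,
                    daily_usage, pooled_connectivity_summary,
                    select_dominant_side, hourly_vectors, wss_curve,
                    elbow_select)

cfg = StudyConfig()
table, truth = simulate_cohort(n_participants=20, n_days=8, seed=7)
table, _ = filter_day_window(table, cfg)

daily = daily_usage(table, cfg)
s = pooled_connectivity_summary(daily)
print(f"median underestimate {s.pooled_median_delta_abs_h:.2f} h, "
      f"median dT_rel {s.pooled_median_delta_rel:.3f}")

dom = select_dominant_side(daily)
vecs = hourly_vectors(table, dom, cfg)
curve, models = wss_curve(vecs.to_numpy(), cfg.kmeans_k_max, restarts=10, seed=1)
k = elbow_select(curve).k
print(f"elbow selects k={k}; explained variance "
      f"{models[k-1].explained_variance:.2f} over {len(vecs)} days")
```

prints

```
median underestimate 0.75 h, median dT_rel 0.112
elbow selects k=4; explained variance 0.67 over 160 days
```

i.e. on this small cohort remote logging undercounts the median day by about
0.75 h (its connectivity ~89%), and the elbow rule recovers the four wear
archetypes the generator planted, with the 4-cluster solution explaining 67%
of the day-to-day variation in hourly usage patterns.

A command-line interface mirrors the library
(`aidlog simulate / validate / convert / preprocess / estimate / cluster /
associate`); run `aidlog --help`.

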