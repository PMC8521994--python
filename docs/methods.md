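# Methods

`aidlog` analyses minute-resolution remote datalogs from smartphone-connected
hearing aids. A log row exists for a minute only when the aid was worn *and*
Bluetooth-connected; alongside each row the device reports its cumulative
on-time counter (seconds since the last reset) and two per-minute acoustic
descriptors, the ambient sound pressure level (SPL, dB) and the estimated
signal-to-noise ratio (SNR, dB). Because the study data this kind of pipeline
targets cannot be shared, the package ships a synthetic cohort generator with
known ground truth; everything below describes both the estimators and what
the generator does and does not emulate.

## Usage estimators and connectivity

Two estimators of daily device use are computed per participant-day-side
within the analysis window [06:00, 24:00):

- **T_remote** counts unique minute-resolution timestamps; each stamp
  represents 60 s of worn-and-connected time. Duplicate or sub-minute stamps
  collapse to one minute.
- **T_intrinsic** sums the positive differences of the cumulative on-time
  counter across consecutive logs, `sum_n (t_n - t_{n-1})`. Because the
  counter advances during connectivity gaps, this recovers true on-time
  between the first and last log of the day. Negative differences mark
  counter resets (clinical visits); they contribute zero and are flagged
  rather than spliced, a deliberately conservative choice.

Their relative difference `dT_rel = (T_intrinsic - T_remote) / T_intrinsic`,
clamped to [0, 1] and undefined when T_intrinsic = 0, measures the fraction
of worn time lost from the remote log; `100 * (1 - dT_rel)` is the day's
connectivity percentage. Pooled medians, a two-stage participant aggregation
(mean within, median across participants), stratification by intrinsic
on-time bins (2-h bins over (0, 18], right-closed), and per-cluster summaries
are provided.

## Inclusion filters

In pipeline order: (1) records outside [06:00, 24:00) are dropped — night
logging is dominated by aids left switched on; (2) participants with fewer
than 2 distinct logging dates (either side) are removed; (3) for day-level
acoustic modelling, a day is dropped when any of its three summaries falls
strictly below the pooled 1% quantile or strictly above the pooled 99%
quantile of that summary (linear-interpolation quantiles, pooled across
participants; under 10 pooled days the filter is a warned no-op). The
outlier rule is day-level and "any violation drops the day", because the
modelling unit is the day. Clustering uses only the side with the higher
daily total, ties broken to the left.

## Daily-pattern clustering

A day's usage pattern is its 18-vector of minutes used per hour, 06:00-24:00,
entered unstandardized (all coordinates share units). K-means (Lloyd,
k-means++ seeding, 25 restarts, 300 iterations max; scikit-learn backend) is
fitted for k = 1..10; the normalized within-SS curve is kept non-increasing
by warm-started refits when a best-of-restarts fit regresses. The cluster
count is selected by an automated elbow rule: the k whose curve point sags
farthest below the chord joining (1, w_1) and (k_max, w_kmax); ties go to the
smaller k, and a perfectly straight curve is flagged "no elbow". A linear
fit through the post-elbow tail is reported as the visual-diagnostic analogue.
Solutions are evaluated with the silhouette coefficient
`SC = (b - a) / max(a, b)` (a: mean distance to own cluster's other members;
b: smallest mean distance to another cluster; singleton-cluster members get
SC = 0 by convention), implemented directly and tested against an O(n^2)
brute-force oracle and scikit-learn.

## Daily acoustics and the association model

Per day-side: the equivalent continuous level
`Leq = 10 log10(mean(10^(SPL/10)))` (energetic mean; always at least the
arithmetic dB mean), the within-day SPL standard deviation (SPLSD, a proxy
for environment diversity), and the daily median SNR. Days with fewer than
10 logged minutes are excluded as unstable.

Daily usage (hours, from T_remote) is regressed on the three predictors,
standardized over the pooled analysis set, with a linear mixed model fitted
by maximum likelihood (statsmodels MixedLM; crossed random effects are
expressed as variance components of a single all-encompassing group,
optimized with Powell's method, which proved far more reliable than gradient
methods on this profiled likelihood). The default random structure:

- random intercepts for participant, day of week, and laterality;
- a **participant-day intercept**: the left and right rows of one wearer-day
  are near-duplicates (same wear episode, same environment), and without a
  shared-day component fixed-effect tests on bilateral rows are severely
  anti-conservative;
- diagonal random slopes for the three predictors within participant, day of
  week, and laterality (9 slope variances).

Wald 95% CIs are reported for the fixed effects. Two likelihood-ratio tests
are available. The *intercept-only* comparison (null keeps the random
intercepts, drops fixed effects and slope variances; df = 12) mirrors the
headline significance test of this literature, but its chi-square reference
is conservative by construction: nine of the twelve tested parameters are
variances on the boundary of the parameter space, and the asymptotic
rejection rate of the true boundary mixture at nominal 5% is below 1%. The
*fixed-effects* comparison (`fixed_effects_lrt`; the null retains the full
random structure, df = 3) is asymptotically exact and is the test used for
type-I-error calibration. Collinearity is diagnosed with plain VIFs (all
predictors continuous, so GVIF reduces to VIF). Variance explained follows
the Nakagawa decomposition for identity links: marginal = var(fixed
predictions) over (fixed + random + residual); conditional adds the random
components; slope components enter as sigma^2 * mean(x^2); the
participant-day component is counted as *unexplained* variance, since the
wearer-day is the unit of interest and that component is exactly the
day-level noise a day-level analysis would leave in its residual. Singular
or non-converged fits drop random slopes progressively (side, then day of
week, then participant), recording the trail.

## Synthetic cohort generator

Each participant draws an archetype preference from the cohort mixture and
follows it on a given day with probability 0.55 (else a fresh draw), so the
marginal archetype frequencies equal the mixture while participants retain
realistic habitual patterns. The four archetypes are: morning (06:30-14:30),
afternoon/evening (12:00-23:00), all-day (07:00-22:30) — each with +/-45 min
uniform edge jitter — and sparse (4-6 epochs of 20-60 min inside
07:00-23:00). With probability 0.35 a day loses one contiguous worn chunk of
30-240 min (aids set aside mid-day); the interruption is applied *after* the
day's acoustic context is planned, so it contributes usage variability that
the environment does not explain. An optional night-contamination flag emits
00:00-06:00 logging for exercising the day-window filter.

Ambient acoustics follow a three-state context chain (quiet /
speech-in-noise / loud-diverse) with persistence 0.97 and stationary weights
that tilt away from quiet on longer-wear days. Per-minute SNR is a shifted
log-normal (shift -2 dB) per state; the speech-in-noise state has the lowest
SNR. Per-minute SPL combines the state level (56 / 64 / 69.5 dB), a
day-level intensity offset (SD 4 dB), and within-state noise (SD 8.5 / 9.5 /
11 dB) scaled by a day-level diversity factor (SD 0.12) — the noise is
negatively skewed (standardized negated log-normal: bounded above, long
lower tail), as minute-level SPL distributions are. This matters: with
Gaussian within-state noise the energetic mean tracks the SD so strongly
that daily Leq and SPLSD become nearly collinear (VIF ~8), whereas published
analyses report VIFs below 1.5. Usage coupling is threefold and mechanistic,
all monotone in planned wear: quiet weight falls 0.022/h from 0.72,
intensity offset rises 0.17 dB/h, diversity rises 0.010/h (all centred at a
9-h reference day; a single `coupling_strength` switch severs all three for
null simulations). These defaults were calibrated once so that day-level
marginals match the field's published values — Leq median ~68 dB (day SD
~5.5), SPLSD median ~10.4 dB, daily median SNR ~3.6 dB (right-skewed,
day-level minimum around 1 dB), ~6-7% of raw SNR minutes at or below 0 dB —
and so that the association stage sees marginal/conditional R^2 near
0.15/0.35 with the (+, +, -) sign pattern.

Connectivity: a device-day's availability is drawn around 0.85 (SD 0.18,
clipped to [0.05, 1]; median exactly 0.85), reflecting the wide between-day
spread of data loss in real remote logs, then applied per worn minute either
independently (Bernoulli) or via a two-state Markov chain with mean
disconnected-burst length 10 min (the default; real outages are bursty).
Sides share the wear mask and environment but have independent connectivity.
The cumulative counter advances for every worn minute, observed or not.

What the generator does *not* emulate: genuinely side-distinct acoustics
(both ears see the same per-minute values), seasonal or day-of-week usage
structure, counter resets mid-study, device or fitting heterogeneity, and
any feedback from sound exposure to next-day behavior. Passing tests
therefore certify the estimators, filters, clustering and inference
machinery under a controlled data-generating process — not the ecological
claims themselves.

## Problem sizes and numerical choices

Simulation-based tests use cohort sizes chosen to keep the full suite
desk-scale while leaving the measured quantities stable: 50 x 10 x 2 sides
(~1,000 device-days) for connectivity recovery; 20 seeds of 20 x 8 cohorts
for elbow recovery; three 40 x 12 cohorts for the association regime; 200
replicates of 8 x 5 null cohorts for type-I calibration; 20 replicates of
25 x 8 cohorts for CI coverage. Quantiles are linear-interpolation
(`numpy.quantile` default). Sample SDs use ddof = 1. K-means ties and
restarts are governed by a single integer seed; all generator randomness
flows from one `numpy` Generator per cohort. dT_rel is clamped to [0, 1];
days with zero intrinsic on-time propagate as nulls and are excluded from
pooled medians.

## Known limitations

Wald CIs without small-sample df corrections undercover when participants
are few (we measured ~0.8 at 12 participants for between-participant
effects); the coverage claims hold at 25+ participants. The intercept-only
LRT's printed p-value is conservative (see above). The elbow rule is an
automated stand-in for a visual judgement and inherits its arbitrariness;
on curves without a clear knee it returns a flagged, weakly-determined k.
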