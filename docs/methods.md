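# Methods

`swipescreen` implements an exploratory digital-phenotyping analysis: do the
kinematics, pressure dynamics and spatial placement of swipe gestures made
while playing casual mobile games track self-reported anxiety and depression
symptoms? The package covers the full path from raw per-swipe event logs and
GAD-7/PHQ-8 item responses to a screened table of feature–symptom rank
correlations, plus a synthetic cohort generator that makes every stage
testable without access to a real cohort.

## Data model and conventions

A **session** is one participant playing one game for at most 15 minutes
(900 s). Three game archetypes are modelled: a **puzzle** game (landscape,
4-direction swipes), an **infinite runner** (portrait, 4-direction swipes)
and an **object slicer** (landscape, long free-angle slicing swipes with no
defined direction). Screen coordinates have their origin at the bottom-left
corner in the session's orientation with y increasing upward, so "swipes start
higher on the screen" means larger y; the default handset is 1080 × 2400 px.

Each swipe carries its full touch path as (t, x, y, press) rows. `press` is a
dimensionless contact-area **pressure proxy** in [0, 1]: capacitive screens do
not measure force, so fingertip contact area stands in for it. Two time
anchors coexist, as in the in-game logger: `event_time` counts from game
launch, `start_time`/`end_time` from the most recent level (or round) load.
`time_between_swipes` is the gap since the previous swipe ended; it is null
for a session's first swipe.

Per-swipe metrics are recomputed from the path by `derive_swipe_metrics`:

* `distance` — sum of consecutive segment lengths ("total screen distance
  covered"), not the net displacement;
* `speed` — `distance / duration`. A `displacement` mode exists for
  sensitivity analysis but the path-length definition is the default, keeping
  speed and distance on the same footing;
* `press_mean`/`press_variance` — over all path points; the start/end pressure
  "variance" is taken over the first/last k = 5 path points (the logger's
  window is not documented anywhere; 5 points ≈ 80 ms at 60 Hz);
* `direction` — dominant-axis rule (|dx| ≥ |dy| → left/right, ties go
  horizontal) for puzzle/runner; always `none` for the slicer.

Sample (n−1) variance/SD is used everywhere a spread is computed.

## Cleaning and outlier removal

1. Swipes whose `event_time` falls outside the session's `gameplay_window`
   are menu interactions and are dropped.
2. Swipes whose total path length is below `min_swipe_distance` (default
   20 px — roughly a fingertip's width; the original threshold is not
   published) are taps or palm touches and are dropped.
3. Each per-swipe metric sequence is filtered with the Tukey IQR rule:
   values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed, with
   linear-interpolation quartiles. Sequences shorter than 4 pass through.

Whether the original analysis applied the IQR filter to per-swipe values or to
aggregated participant-level features is ambiguous; both are implemented
(`iqr_scope = per_participant_metric | pooled_metric`) and the per-swipe scope
is the default, because outliers in trace data arise per event (mislogged
swipes), not per participant.

## Feature catalog

Aggregation turns one cleaned session into one feature vector:

| block | bases | aggregators | count |
|---|---|---|---|
| per-swipe scalars | start/end pos X/Y, start/end press, start/end press variance, press mean, press variance, speed, duration, distance (13) | mean, median, max, min, SD, range, first, last | 104 |
| pooled path positions | posX, posY over every touch point | SD, min, max, range | 8 |
| inter-swipe gaps | time_between_swipes | mean, median, SD, min, max, range | 6 |
| direction counts (puzzle/runner only) | swipe_count_up/down/left/right | — | 4 |
| sensors | acl/gyro × X/Y/Z | mean, median, SD, min, max, range | 36 |
| total swipes | swipe_count | — | 1 |

Totals: 159 features for puzzle/runner, 155 for the slicer — inside the
~150-per-game band the source analysis reports. Composition choices where the
original list is not enumerated: pooled path positions get only spread/extreme
aggregators (their mean/first/last duplicate the start/end position bases);
inter-swipe gaps drop first/last (boundary gaps reflect menu-transition timing,
not gameplay rhythm); sensor streams get six aggregators because "first/last"
are meaningless for a free-running 50 Hz stream. Sensor streams are aggregated
without IQR filtering — their extremes (e.g. the minimum axis acceleration)
are part of the device-motion signal, not event noise.

Sessions with zero swipes report every swipe feature as missing and
`swipe_count` 0.

## Correlation screen

With ~150 features per game, many are near-duplicates. Features linked by
pairwise-complete Pearson |r| ≥ 0.90 are grouped by **connected components**
(a "group" may chain through intermediates; greedy pairwise pruning would be
order-dependent) and each group keeps one representative. Representatives are
chosen by an interpretability priority — speed bases, then pressure-SD, then
pressure-variance, then position, then distance/duration bases — with a
lexicographic tie-break; this encodes the preference for clinically
interpretable kinematics (speed subsumes distance and duration) and for SDs as
variability measures. Whether the original threshold was signed or absolute is
unstated; absolute |r| is used since anti-correlated duplicates are equally
redundant.

Every retained feature is tested against both instrument totals with
**Spearman rank correlation**: Pearson correlation of mid-ranks (average ranks
on ties), two-sided p from the t approximation with n−2 df for n > 9 and full
permutation enumeration for n ≤ 9. Constant inputs yield an undefined result
and are excluded. P values are **uncorrected** by default — the screen surfaces
candidates for confirmatory follow-up rather than testing prespecified
hypotheses — with an optional Benjamini–Hochberg mode.

## Questionnaires

GAD-7 (7 items, total 0–21) and PHQ-8 (8 items, total 0–24) are summed
directly; items are 0–3 frequency ratings. Severity bands default to the
instruments' canonical cutoffs (0–4 none, 5–9 mild, 10–14 moderate, ≥15
severe), with PHQ's "moderately severe" and "severe" collapsed so both
instruments use four bands; cutoffs are configurable because published cohort
tables do not always state them.

## Synthetic cohort generator

The generator emulates the *statistical structure* of such a study, not the
games: latent severity drives both questionnaires and swipe behaviour.

**Latent traits.** Each participant has (z_dep, z_anx) ~ bivariate standard
normal with correlation 0.6 (configurable; anxiety and depression screeners
typically correlate 0.5–0.7 in community samples, and the reference cohort
reports no inter-score correlation).

**Item responses.** Each item is a clamped discretisation of the trait:
`item = clamp(round(a + b·z + s·ε), 0, 3)` with per-item noise s = 0.9.
Items are conditionally iid given z, so the total's mean, variance and
covariance with z are one-dimensional Gaussian integrals; (a, b) are solved by
Gauss–Hermite quadrature plus root finding so the population totals hit the
configured targets exactly (defaults: GAD-7 mean 9.09, SD 5.26; PHQ-8 mean
8.24, SD 4.95 — the reference sample's statistics). No simulation is involved
in this calibration. The solved models imply corr(z, total) ≈ 0.91 (GAD-7)
and ≈ 0.88 (PHQ-8), the measurement ceiling any planted behavioural effect
must pass through.

**Participant swipe parameters.** Each drivable parameter (median swipe speed;
per-point pressure jitter, which sets end-of-swipe pressure variance; mean
pressure level; swipe start-height centre) deviates from its game base by a
**unit-variance driver** `u = w_dep·z_dep + w_anx·z_anx + w_noise·ε`, applied
through a log link for positive-only parameters (speed ×e^0.18u, i.e. ±18%
per SD) and additively for bounded ones (pressure level ±0.06, start height
±60 px). Because u always has unit variance, planting an effect changes only
the correlation structure, never the marginal spread of behaviour.

**Sessions.** Swipes tile the gameplay window (5–895 s) as a renewal process:
gap ~ lognormal plus the swipe's own duration, with the gap scale set so the
expected count matches the configured target (350 puzzle / 500 runner / 400
slicer — enough swipes for stable aggregates over 15 minutes). A renewal
process was chosen over an unconditional Poisson count so that slower swipers
complete fewer swipes, reproducing the empirical negative swipe-count/severity
association, and so swipes never overlap. Paths are bowed line segments
sampled at ~60 Hz during contact with 1.5 px jitter, length lognormal (median
300/350/600 px; the slicer's slices are deliberately longer), clipped into the
screen; per-point pressure is the participant's level plus a small mid-swipe
arch and jitter. Puzzle/runner directions are axis-aligned draws (the runner
favours "up"); the slicer draws free angles. Accelerometer/gyroscope streams
run at 50 Hz: a gravity baseline per orientation plus participant-amplitude
postural sway (shared 0.15–0.45 Hz sinusoids) and wideband noise, stored as
float32 (ample for motion telemetry).

All per-swipe quantities stored in generated logs are computed by the same
formulas as `derive_swipe_metrics`, so re-deriving from the stored path
reproduces the stored values to 1e−6 (tested).

**Planted effects.** A target Spearman rho between a feature and an
instrument total is reached in two steps. Analytically: convert the target to
the latent Pearson scale via Greiner's relation r = 2·sin(πρ/6), divide by the
instrument's latent-total correlation and by the mechanism's **attenuation
factor** λ (losses from session aggregation, cleaning/IQR, order-statistic
noise in min-features, and the rank conversion on discrete totals), then solve
the 2×2 linear system for (w_dep, w_anx) given the trait correlation —
infeasible targets (driver variance ≥ 1) raise a diagnostic error. λ itself is
estimated by Monte-Carlo (`calibrate_effect` runs the full pipeline over
replicate cohorts and rescales λ by the measured-to-target ratio on the latent
scale); the shipped `ATTENUATION` table holds the calibrated values for the
default effect map and can be regenerated with `scripts/calibrate_defaults.py`.

The default effect map plants only each game's strongest associations (puzzle
speed and end-pressure variance, runner end-pressure variance, slicer start
height and pressure floor, each against both instruments where the reference
analysis reports both) rather than every reported row: most remaining rows are
correlated consequences of the same mechanisms — e.g. planting lower speed
automatically produces longer durations, lower speed minima/maxima and fewer
swipes.

**What the generator does not emulate** — and hence what a green test does
not establish: no game logic (mazes, obstacles, scoring), no learning or
fatigue drift within or across sessions, no demographic or gaming-experience
moderation of swipe behaviour, no device heterogeneity, no missing sessions,
and the trace noise is well-behaved (lognormal/Gaussian) rather than
real-world heavy-tailed. Recovery of a planted effect demonstrates that the
pipeline's cleaning, aggregation and screening preserve a monotone
trait-behaviour signal of the published magnitude at n = 78; it cannot
validate the psychological claims themselves.

## Numerical choices

* Quartiles: linear interpolation (NumPy default); Tukey multiplier 1.5.
* Direction ties (|dx| = |dy|) go to the horizontal axis; zero displacement is
  a tap and is rejected before direction is computed.
* SD/variance: ddof = 1 throughout; SD of a single value is missing (NaN);
  a single-point pressure window has variance 0.
* Spearman: exact enumeration up to n = 9 (two-sided, with a 1e−12 guard on
  the comparison); t approximation above; p values floored at the smallest
  positive double so reported p ∈ (0, 1].
* Collinearity grouping uses |r| ≥ threshold − 1e−12 to make the boundary
  deterministic.
* Item discretisation uses thresholds at 0.5/1.5/2.5 (floor(x + 0.5)), exactly
  matching the quadrature used in calibration.
* Seeds: a cohort is a pure function of its config; per-participant and
  per-session RNG streams are spawned from the root seed, so cohorts are
  reproducible at every granularity and byte-identical on disk.

## Known limitations

* The feature catalog's exact composition is a reconstruction; the original
  ~150-metric list is not enumerated in the source material. Counts (159/155
  per game) land in the reported band but individual entries may differ.
* The attenuation table is calibrated for the default generator configuration;
  materially different session lengths, swipe counts or noise scales require
  re-running `scripts/calibrate_defaults.py` (or `calibrate_effect`).
* With n = 78 and α = .05 uncorrected, ~5% of null features pass the screen by
  construction; the screen is exploratory by design.
* The pooled-metric IQR scope and displacement-based speed are provided for
  sensitivity analysis but are not the defaults and are less thoroughly
  exercised by the acceptance suite.
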