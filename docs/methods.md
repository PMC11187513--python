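# Methods

## The measurement problem

Rest-activity rhythms are usually measured with wrist actigraphy. The
app-count method treats human-smartphone interaction as an alternative
behavioural trace: when a person is asleep they do not generate screen
events, so the event stream carries the same near-24-hour structure as
wrist movement. rhythmkit implements both pipelines over one shared
container — a regularly sampled nonnegative count series with a validity
mask (`EpochSeries`) — so that indicators from the two modalities are
directly comparable per participant.

All timestamps are timezone-naive local wall-clock; daylight-saving
transitions are out of scope. Missing data is always a masked epoch,
never a zero: a zero count is a meaningful observation (no interaction,
no movement). Epochs are half-open `[t, t + epoch)` and events are
floored into the containing epoch. Days are segmented anchor-to-anchor
(default anchor: local midnight, configurable); partial first/last days
are excluded from day-level statistics.

## App-count pipeline

1. **Counting.** Every interaction event (screen on/off, app use) adds
   one to its minute; minute counts are summed into 5-minute epochs
   (288/day). Notification arrivals are passive rather than user
   actions, so they are excluded from counts by default
   (`include_notifications=True` restores them).
2. **Cycle extraction.** The epoch series is band-passed to periods of
   16–24 h with a second-order-section Butterworth applied forward and
   backward (zero phase, so sleep timing is not delayed). The series is
   extended by two days of circular (wrap-around) padding before
   filtering: the signal of interest is near-day-periodic, and periodic
   extension keeps the phase of the first and last day intact, whereas
   mirror reflection leaves a trough drift of 2–3 h on the edge days
   because the filter transient is long at a 24 h corner (measured on a
   7-day square wave: troughs 3.7–4.25 h with wrap padding vs 1.2–6.6 h
   with reflection, against a 4.0 h ground truth).
3. **Inactive window.** Per calendar day, the window is the half-cycle
   centred on the filtered signal's trough — trough ± a quarter of the
   dominant period (FFT peak of the filtered series) — clipped to
   [4 h, 16 h]. A constant series has no detectable cycle and is an
   error. Each window is dated by the noon-to-noon day containing its
   trough, i.e. by the evening the night starts.
4. **Run-length detection.** Onset is the *start* of the first run of
   ≥ 8 zero-count epochs in the window; wake is the *start* of the first
   run of ≥ 6 nonzero epochs after onset (window end if none); nonzero
   epochs between onset and wake count 5 min each toward WASO, including
   runs shorter than 6 epochs. Using the run start (earliest evidence)
   rather than its completion keeps onset/wake unbiased relative to the
   run rules; both run lengths are configurable because falling asleep
   mid-use inflates detected onset and a stricter zero-run can
   compensate.

Decimal-time convention: episode times are hours past the midnight of
the night's date, with times after that midnight carrying +24 (00:21 →
24.35), so averaging onsets across nights never wraps.

## Actigraphy pipeline

* **Counts.** Per-sample Euclidean norm of the three axes → 0.5–3 Hz
  band-pass (zero-phase SOS Butterworth; any filter within ±1 dB of that
  response in-band is considered conforming) → absolute value, with
  magnitudes below a noise dead-band (default 0.01 g) zeroed →
  integration over nonoverlapping 2-s windows → the per-minute count is
  the mean of the 30 window values. Sampling below 6 Hz cannot represent
  the passband and is rejected.
* **Wear detection.** Runs of counts ≤ threshold (default 0: exact
  zeros) lasting ≥ 30 min are off-wrist; a day with > 360 min off-wrist
  is invalid and excluded from every downstream indicator. Both the
  run length and the count threshold are configuration, since devices
  differ in their noise floors.
* **Cole–Kripke scoring.** The published 1-minute-epoch weights
  (106, 54, 58, 76, 230, 74, 67 over minutes −4…+2, scale 0.001,
  criterion D < 1) are the defaults; weights, scale and criterion are
  exposed so device-specific recalibrations can be expressed. Boundary
  minutes use zero-padded neighbours; off-wrist minutes are invalid and
  contribute zero to neighbours' sums. For a constant count c the sleep
  condition reduces to c < 1/(0.001·665) ≈ 1.50, which the tests use as
  a closed-form oracle.
* **Episodes.** Within a night window (default 18:00–12:00) sleep runs
  ≥ 20 min consolidate across wake gaps ≤ 120 min; the longest block
  (ties → earlier onset) is the main episode and must reach 60 min —
  the minimum excludes naps from putative night sleep. WASO is the
  wake-scored minutes inside the block. The weighted window smears
  block edges by construction (≈ +4 min at onset, −2 min at wake for
  high surrounding activity), so TST from scoring runs ~6 min short of
  the nominal span; this is a property of the scoring algorithm, not a
  defect of the implementation.

## Nonparametric indicators

IS and IV are computed on hourly-binned data (p = 24) for both
modalities; app-counts are summed 12 epochs → 1 hour first (sum vs mean
only rescales, and both statistics are affine-invariant). IS follows the
variance-ratio formula N·Σₕ(x̄ₕ−x̄)²/(p·Σᵢ(xᵢ−x̄)²); with complete equal
days the law of total variance bounds it in [0, 1], and floating-point
excursions are clipped with a log message. IV is the normalized mean
squared successive difference; with masked gaps, difference pairs that
span an invalid epoch are skipped and the pair count in the denominator
shrinks accordingly. For iid data E[IS] ≈ (p−1)/(pd−1) ≈ 1/d over d days
and E[IV] ≈ 2; for an hourly-sampled sinusoid IV ≈ 2(1−cos ω) — the test
suite uses all three as oracles. Fewer than 7 complete days triggers a
low-confidence warning rather than an error. Relative amplitude and
cosinor fits are deliberately not provided: app-counts lack the
continuous variation both assume.

M10/L5 slide 10-h/5-h windows at epoch stride with wrap-around at the
day boundary; windows containing any invalid epoch are not candidates,
and a day where contamination removes every candidate is skipped.
Participant-level onsets are averaged circularly.

Social jet lag classifies a night by the morning it ends on: free nights
end on Saturday or Sunday (configurable). It needs ≥ 2 nights in each
class, otherwise it is reported unavailable rather than zero.

## Synthetic generator

`simulate_pair` draws, per night, an onset = mean_onset + N(0, jitter)
(+ weekend delay on nights ending Sat/Sun) and a duration
N(mean, sd) clipped to [2 h, 15.9 h]; night awakenings arrive as a
Poisson number of fixed-length intervals inside the sleep period. From
that single schedule it emits both modalities: smartphone events as
per-minute Poisson counts (day rate awake and during awakenings, night
rate asleep) and wrist counts as Gamma(shape 2) draws around the state's
level. Defaults: 28 days (a four-week recording), onset 23.5 h, jitter
0.5 h, sleep 7.5 ± 0.5 h, one 15-min awakening per night, day usage
60 events/h, night usage 0, day activity 150 counts/min, night activity
0.5 counts/min. The day usage rate of one event per awake minute mirrors
the dense event streams a background usage tracker records and makes the
probability that an awake 5-min epoch is nonzero ≈ 1−e⁻⁵; the night
activity level of 0.5 sits well below the Cole–Kripke constant-count
sleep threshold (≈ 1.5), as real night-time wrist counts do. Optional
config blocks inject naps and off-wrist gaps (default off) to exercise
the exclusion logic.

What the generator does *not* emulate: bursty/heavy-tailed usage
sessions, app-category structure, weekday routines beyond the weekend
delay, gradual phase drift, device clock error, or any attempt to match
a real cohort's distributions. Passing recovery tests therefore shows
the pipelines invert the generator's schedule under Poisson/Gamma noise,
not that they are validated against polysomnography.

Known, deliberate recovery biases at the defaults: detected app onset
lags truth by 0–5 min (the first fully-zero epoch); awakenings lasting
≥ 30 contiguous minutes satisfy the 6-epoch wake rule and truncate the
night (the method's documented failure mode when users interact with the
phone at night); WASO counts whole epochs and so over-covers interval
edges. Together these leave a cohort-level TST under-estimate of
≈ 10–15 min and an onset MAE of ≈ 3–4 min, which the acceptance suite
checks at 20 participants × 28 days.

## Statistics

Power for the balanced k-group omnibus one-way ANOVA F test uses the
noncentral F distribution with λ = f²·N (scipy's `ncf`); at f = 0 the
central F is used so power equals α exactly. The sample-size search
enforces equal allocation — N a multiple of k, at least 2 per group —
which is the convention of standard power software and the only reading
under which a planning table of very large effects floors at 2 per
group. The regression reporter z-scores response and predictors,
fits OLS (statsmodels), and returns standardized betas, SEs, p values
and adjusted R²; rank-deficient designs raise an error naming the
collinear columns. Monte-Carlo ANOVA rejection rates serve as the
independent oracle for the power function in the tests.

## Problem sizes in the test suite

Recovery checks run at 20 participants × 28 days; the jitter→IS
monotonicity grid at 6 jitter levels × 20 replicates × 14 days; the
two-group IS-ordering check at 100 cohort replicates of 5 + 5
participants × 14 days (the jitter contrast 0.2 h vs 2.0 h separates
group mean IS by ≈ 0.5, so ordering is near-certain at this size). The
IS-bound battery uses 1,000 randomized hourly series of 7–28 days plus
exact day-periodic inputs. These sizes are the package's own choices,
balancing statistical resolution against a test run of a few minutes.

## Limitations

* The app method assumes not-using ⇒ asleep during the inactive
  half-cycle; shift work, night feeding, or phone abstinence violate it.
* Cole–Kripke weights were calibrated for a particular device family;
  other devices need recalibrated weights (exposed in config).
* The off-wrist detector cannot distinguish motionless wear from
  removal when counts are exactly zero for long spans.
* IS/IV on fewer than 7 days are reported but unstable.
* Sample-size results assume the fixed-effects omnibus model with
  homogeneous within-group variance.
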