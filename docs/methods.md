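# Methods

## Design of the analysis

The pipeline treats a pre/post natural experiment as a fixed calendar: study
weeks are consecutive 7-day blocks anchored at a Monday `study_start_date`;
weeks before `closure_week` are the *pre* period and the rest are *post*.
Anchoring at a Monday makes weekday/weekend day counts within a study week
exactly 5 and 2, which the weekly weighting relies on. All timestamps are
timezone-naive local wall-clock time; a daylight-saving transition inside the
study span is simply treated as a wall-clock day, because every rule in the
chain (the 9 AM–9 PM window, calendar-day boundaries) is a wall-clock rule.

## Wear processing

**Epochs.** Minute samples are aggregated onto a fixed 15-minute grid
anchored at midnight (:00/:15/:30/:45). Steps are summed, motion intensity is
maxed, and the number of observed minutes is recorded. Grid cells inside the
observation span with no data are emitted as zero epochs so the run-length
rule below sees an unbroken sequence; device exports routinely omit idle
minutes, and an absent minute is indistinguishable from a zero one at this
stage. Wear status is decided afterwards from intensity, never at the minute
level.

**Nonwear.** An epoch is nonwear iff it belongs to a maximal run of at least
3 consecutive epochs (45 min) with zero maximum motion intensity. Runs are
evaluated within each calendar day: a zero run spanning midnight is split at
midnight before the length test, because the day is the analysis unit and
cross-midnight behaviour is otherwise ill-defined. A consequence worth
knowing: any epoch with nonzero intensity is always wear.

**Valid days.** A day is valid iff (a) worn epochs whose start lies in
[09:00, 21:00) cover ≥480 minutes — the half-open convention makes the window
exactly 48 epochs = 720 min — and (b) total steps over *worn* epochs of the
whole day are ≥500. The step clause is deliberately not restricted to the
window: the two clauses are independent, the time window qualifying only
wear time. Because zero-intensity epochs carry zero steps by construction,
masking nonwear epochs out of the step total is a consistency choice with no
numeric effect (asserted by test). Days with no observed epoch at all are
omitted rather than emitted as invalid: "never synced" is not the same
observation as "worn but inactive".

**MVPA minutes.** Consumer devices report "active minutes" from a
proprietary classifier; we operationalize the documented behaviour — credit
for running ≥1 minute or walking ≥10 consecutive minutes — through cadence.
A minute with cadence ≥130 steps/min is a running minute and always counts
(run bout length 1); a minute with cadence in [100, 130) is a walking minute
and counts iff it lies inside a maximal stretch of ≥10 consecutive non-idle
(walk-or-run) minutes. The walk-or-run reading of contiguity was chosen over
walk-only contiguity so that a walker who briefly breaks into a run does not
forfeit the bout; both readings agree on homogeneous bouts. A gap in the
minute record breaks any bout. All four thresholds (walk 100 and run 130
steps/min; bout lengths 10 and 1 min) are configuration parameters, so
sensitivity to the cadence cut-points can be tested; the defaults are the
conventional ambulation bands (100 steps/min ≈ moderate walking, 130 ≈
running).

## Weekly aggregation

Per participant-week, a week is *valid* with ≥1 valid day. For valid weeks
the daily value is the 5/2-weighted combination of the valid-weekday mean and
the valid-weekend-day mean; when either class is absent the fallback is the
unweighted mean over all valid days. The weights sum to 1, so the weighted
value always lies between the two class means and collapses to the common
mean when they agree. MVPA is carried per day through the weighting and
reported per week as 7 × the weighted daily value, reconciling the daily
scale on which days are aggregated with the weekly scale on which the
outcome is conventionally reported (≈11.5 min/day ↔ ≈80 min/week). Weekly
values are carried at full floating precision; rounding happens only at
report time.

Participants enter the analysis with ≥1 valid week in the pre period and ≥1
in the post period. The filter is monotone: adding a valid week can only add
participants.

## Models

Each outcome (steps/day, MVPA min/week) is modelled on valid weeks with a
linear mixed model: fixed effects for period (or categorical study week,
reference = earliest week) plus the number of valid weekday and weekend wear
days in the week; a participant-level random intercept; REML estimation so
that participants contribute whatever valid weeks they have without
imputation. The random-intercept structure is the minimal faithful encoding
of weeks nested within participants — a cohort of ~17 cannot identify richer
covariance structures.

Estimated marginal means are computed at the sample means of the wear-day
covariates with model-based standard errors, and 95% CIs use the t
distribution on the containment-style denominator df
`n_obs − n_groups − k_fixed + 1`; the same df enters the Wald F tests. The
df method is recorded on every result object. No Satterthwaite or
Kenward-Roger correction is applied (not available in the fitting backend);
with dozens of week observations the practical difference is small, and
reported df should be read as approximate. Percent change is
100 × (post − pre)/pre on the estimated means, rounded half away from zero
to one decimal. Significance is two-sided at α = 0.05.

Two degenerate regimes are handled explicitly: constant wear-day covariates
are dropped from the design (they are collinear with the intercept), and a
zero-variance outcome short-circuits to the exact answer (all means equal,
F = 0), since REML is undefined there.

Demographic comparisons of included vs excluded participants use the Pearson
chi-square without continuity correction; categories with zero total count
are dropped first (the test is undefined on structural-zero margins) and df
reflects the reduced table.

## Synthetic cohorts

The generator emulates the study conditions, not just any wearable data:

- **Scale and timing.** 17 participants, 8 Monday-anchored weeks, closure at
  week 5 (defaults; all configurable).
- **Activity levels.** True participant means are unit-mean lognormal
  multipliers (positive skew of step counts) around 8003 steps/day and
  11.45 MVPA min/day (= 80.18 min/week) pre-closure; from the closure week
  every mean is multiplied by 0.546 (steps) and 0.575 (MVPA). Weekdays run
  ~25% above weekend days (`weekend_step_ratio` 0.8), with the 5/2-weighted
  overall mean held exactly at the configured level.
- **Day values.** Day targets are normal around the participant-day mean
  (SD 1800 steps, 3.5 MVPA min), clipped at zero with the location shifted
  so the clipped draw keeps the configured mean exactly — without the shift,
  clipping would bias small post-closure MVPA means upward by ~1% and
  contaminate ratio-recovery checks.
- **Minute structure.** A worn day is a block from ~7:30 to ~21:45 with at
  most one 45–75-min off-body gap; MVPA is placed as one contiguous 10-min
  walking stretch (when the budget allows) plus running minutes, each minute
  drawing its cadence from the configured band; the residual step budget is
  spread over other worn minutes at sub-walk cadence (≤99 steps/min); idle
  worn minutes get motion intensity 1 and zero steps; non-worn minutes are
  absent from the export.
- **Missingness.** Each day is worn with probability 0.75 (so a valid week
  averages ~5.25 valid days, matching the ~5.2 observed in this kind of
  cohort), and each participant independently stops producing any
  post-closure data with probability 0.2 — the all-or-nothing sync-dropout
  mechanism by which remote data collection loses whole participants.
- **Reproducibility.** One global seed spawns per-participant seed
  sequences; identical seeds give byte-identical exports.

A week-level companion (`generate_week_summaries`) draws valid-week outcomes
directly from the same generative structure (binomial valid-day counts,
day-level noise averaged through the 5/2 weighting) without materializing
minutes. Model calibration and parameter-recovery simulations run on this
fast path (200 recovery cohorts of 40 participants; 500 null replicates);
the minute-level path is exercised end to end at 50 replicate cohorts of 17,
which recovers the configured pre-closure level. The acceptance script pools
20 minute-level cohorts.

What the generator does **not** emulate: circadian microstructure and
school-timetable effects beyond the weekday/weekend contrast, week-level
sync gaps among retained participants (real cohorts show fewer valid weeks
per included participant than the generator produces), device firmware
quirks, and any distributional detail beyond means and variances — the
source study reports only means and SEs, so variance parameters are modeling
choices. Passing tests therefore demonstrate correctness of the pipeline's
rules and calibration of the models under plausible conditions, not fidelity
to any particular cohort's microdata.

## Numerical notes

- Epoch aggregation conserves steps exactly (integer arithmetic).
- The wear mask and MVPA counters are vectorized run-length scans; tests
  compare them against independent window-enumeration oracles, exhaustively
  for all patterns of length 12.
- Wald F uses `solve` on the contrast covariance rather than explicit
  inversion; singular fits raise a diagnostic error instead of returning
  garbage.
- The chi-square helper and the mixed-model fitter are thin layers over
  scipy/statsmodels; everything upstream of them (filtering, weighting,
  inclusion) is implemented here and is the part covered by exhaustive
  oracles.

## Known limitations

- Denominator df are containment-style, not Satterthwaite; CIs on estimated
  means ignore uncertainty in the variance components.
- The MVPA rule is a cadence proxy for a proprietary classifier; activities
  that accumulate "active minutes" without ambulation (e.g. cycling) are
  invisible to it.
- The ≥500-step clause uses whole-day worn steps by design; cohorts with
  heavy out-of-window activity would classify days slightly differently
  under a window-restricted reading.
- With one valid day a week's value rests on a single observation; the
  wear-day-count covariates in the models are the only adjustment for this
  heteroscedasticity.
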