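# Methods

## Data model

All computation operates on a per-participant minute grid: one row per
calendar minute, channels `steps` (count/min), `heart_rate` (bpm) and
`kcal` (kcal/min). Non-wear is *defined* as the absence of a heart-rate
reading; when heart rate is absent the other channels are blanked as well,
since a device off the wrist measures nothing meaningful. Missingness is
always channel absence, never a missing row, so hour/day arithmetic is pure
array reshaping. Timestamps are timezone-naive local time; a "weekend day"
is a Saturday or Sunday of the timestamp's calendar date; 14-day windows are
anchored at the series start. Series are exchanged as plain CSV
(`participant_id,age,sex,timestamp,steps,heart_rate,kcal`) with empty cells
for missing values; reads use round-trip float parsing so write→read is
bit-exact.

## Wear-time scaling

The scaling cascade extrapolates partial-wear intervals under the working
assumption that, within an hour, activity during unworn minutes resembles
activity during worn minutes (justified empirically by the strong short-lag
autocorrelation of minute-level heart rate and, more weakly, steps):

| level | validity threshold | estimator |
|---|---|---|
| hour | ≥ 5 worn minutes | observed sum ÷ (worn/60) |
| day | ≥ 18 valid hours | sum of scaled hours ÷ (valid hours/24) |
| 14 days | ≥ 4 valid days incl. ≥ 1 weekend day | mean of valid scaled days |

Invalid units carry no value (NaN), never zero, and are excluded pairwise
from evaluation. Two deliberate readings of ambiguous points: the daily step
consumes *scaled* hourly totals (this makes the two scalings compose, and is
exact whenever within-day activity is uniform), and heart rate itself is
never scaled — scaling applies only to accumulable quantities, with time-in-
category handled by scaling the per-minute 0/1 category indicator, which
guarantees the four scaled category minutes sum to 60 per valid hour and
1440 per valid day. The "removal" comparator sums observed minutes with no
adjustment and no screening, implicitly treating missing minutes as zero.

## Intensity classification

Anchors are per participant: HRmax from the Tanaka equation 208 − 0.7·age;
sleeping HR as the minimum, over all nights pooled, of the mean of 20
consecutive minutes between 00:00 and 07:59 with steps < 5 and heart rate
present (windows never span 07:59→00:00 and skip any missing-HR minute);
HRrest = 1.08 × sleeping HR. The printed category boundaries overlap at
20/40/60 %HRR, so half-open-on-the-left intervals are adopted: sedentary
(−∞, 20), light [20, 40), moderate [40, 60), vigorous [60, ∞). If a
participant has no qualifying sleep window (e.g. shift workers) the module
raises rather than guessing a fallback. In the simulation pipelines each
participant's anchors are computed once from the complete series and reused
for truth and for every method, so category comparisons measure imputation
error rather than anchor drift.

## Imputation methods

* **Mean imputation** — observed channel mean, pooled over the cohort
  (overall) or the participant (individual).
* **Multiple imputation (bootstrapped PMM)** — per imputation: bootstrap the
  observed minutes, fit an ordinary-least-squares linear predictor
  (overall scope: age, sex, day-of-week indicators, pooled over the cohort;
  individual scope: day-of-week and hour-of-day indicators), and fill each
  missing minute with the observed value of one of the k = 5 donors whose
  predictions are nearest its own, chosen uniformly. Defaults m = 5
  (overall) and m = 7 (individual). Point summaries average the m completed
  datasets' summaries; Rubin's variance rules are out of scope because only
  point RMSE/means are evaluated. The donor pool, main-effects predictor
  and bootstrap-per-imputation are this package's dialect of the PMM class,
  not a numeric reproduction of any particular R package.
* **Random forest** — iterative imputation: initialise missing entries at
  the channel mean; revisit channels in order of increasing missingness,
  refitting a scikit-learn `RandomForestRegressor` (100 trees, √p features
  per split, minimum leaf 5 — the classic regression-forest node size) on
  weekday, hour and the other channels' current values; stop when the
  aggregate relative change between successive imputations stops
  decreasing, or after 5 iterations, keeping the last improving pass.
* **Kalman smoothing** — per channel, a Gaussian local-level structural
  model (random-walk level variance q, observation-noise variance r) fit by
  maximum likelihood via `statsmodels` `UnobservedComponents`; missing
  minutes take the smoothed state mean. The local-level family (no trend or
  seasonal term) reflects the dominance of local correlation at the minute
  scale; a stochastic daily seasonal can be enabled via `seasonal_period`
  but is off by default and expensive. A constant observed channel is the
  degenerate q = r = 0 model and is filled with the constant directly.

All imputers leave observed minutes bit-identical, clip imputed steps/kcal
at 0 and imputed heart rate to (25, 250) bpm. Category metrics are never
imputed directly: heart rate is imputed, then classified.

## Missingness simulation

Study 1 inserts 40 independent periods per participant: start uniform over
the 20160-minute grid, integer length uniform on [1, 120] minutes,
truncated at the series end, applied as a union (overlaps are permitted;
independent uniform draws are the simplest reading of random insertion, and
the implied mean inserted fraction, 1 − (1 − 60.5/20160)⁴⁰ ≈ 11.3%, matches
the design's reported scale). Study 2 sweeps windows w = 1…10 with the
period count drawn uniformly from {10(w−1), …, 10w}, 20 simulations per
participant per window at full scale.

## Evaluation

RMSE pools participant-hours at the hourly level, participant-days at the
daily level and participants (one value each) at the 14-day level.
Equivalence is the paired TOST: with d = imputed − true and bound =
0.1 × mean(true), p_upper tests H0: mean d ≥ +bound and p_lower tests
H0: mean d ≤ −bound by one-sided paired t-tests; declaring equivalence when
both p < 0.05 is identical to the 90% confidence interval of the mean
difference lying inside ±bound (verified exhaustively in tests). A
zero-variance difference vector is judged directly against the bound with
p reported as 0. ICC is the two-way mixed-effects, absolute-agreement,
single-measure form, computed from the closed-form ANOVA decomposition
ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) and cross-checked
against both a brute-force sums-of-squares oracle and `pingouin`.
Wear-time-requirement curves delete data incrementally (minutes within
hours, scaled; whole hours per day and whole days per fortnight, unscaled)
and report ICC against truth, with 0.9 as the adequacy threshold. Trend
claims ("RMSE grows with missingness") use a one-sided paired sign test
across participants rather than strict per-window ordering, since
Monte-Carlo noise can invert adjacent windows.

## Synthetic cohort generator

The generator emulates the *shape* of free-living wrist-monitor data, not
its physiology: a nightly sleep window (default 23:00–07:00) with zero
steps and Normal(sleeping HR, σ) heart rate; waking minutes with Poisson
steps at a sedentary baseline cadence (default 4 steps/min); activity bouts
arriving as a per-day Poisson process with uniform lengths (5–40 min) and
cadences (25–115 steps/min) that never run into sleep; heart rate =
HRrest + 0.9·(cadence/peak)·reserve plus stationary AR(1) noise
(coefficient 0.8 — chosen so short-lag autocorrelation is clearly higher
for heart rate than for steps, as in real minute data); energy =
basal·(1 + 4·steps/peak cadence). The bout rate is calibrated per profile by
inverting the expected Poisson-process coverage of waking time, so mean
daily steps land within a few percent of the target. Cohort defaults centre
on a middle-aged, mostly female weight-loss-maintenance population
(age ≈ 47 ± 10, ≈ 10,500 steps/day, TDEE ≈ 2,600 kcal/day).

What it does **not** emulate — and hence what passing tests do not show
about real data: behavioural (informative) non-wear, weekday/weekend
differences, gradual HR drift, device error, or a realistic light-activity
budget (non-bout waking minutes sit near resting HR, so light minutes are
far fewer than typical free-living HRR classifications). Conclusions here
are about the estimators under missing-completely-at-random insertion, not
about device validity.

## Problem sizes and numerical choices

The packaged experiments run at desk scale: the cohort-level acceptance
checks use n = 30 participants for the fixed-missingness study and n = 8
participants × 2 simulations per window (windows 1 and 10) for the
incremental study, sizes chosen so the full suite completes in a few
minutes on one CPU while leaving the sign tests adequately powered; the
full-scale designs (n = 109, 20 simulations, all ten windows) are available
through the same functions. Kalman fits use L-BFGS with at most 100
iterations; occasional non-convergence warnings at flat likelihoods are
benign (the smoothed level is insensitive), and a non-finite likelihood
raises. PMM donor search sorts donors once per imputation and scans a 2k
window around the insertion point. All randomness flows from explicit seeds
through `numpy` `SeedSequence` spawning, so every pipeline is reproducible
bit-for-bit and stages can be re-run independently.

## Known limitations

* The overall-scope multiple-imputation model pools all participants'
  minutes into one regression (stratification is a plausible alternative
  reading and is not implemented).
* Mean/MI/forest imputers ignore gap topology (they fill a 2-hour gap the
  same way as 40 scattered minutes); only the Kalman smoother and the
  scaling cascade exploit temporal adjacency.
* The equivalence criterion's bound depends on the observed criterion mean,
  so verdicts at small n are sensitive to cohort composition.
* Time-of-day–weighted or informative missingness is out of scope by
  design; insertion is uniform over the grid.
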