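# wearimpute

Wear-time scaling and imputation for minute-level data from commercial
activity monitors.

Wrist-worn monitors (e.g. heart-rate-enabled Fitbit-class devices) record
steps, heart rate and energy expenditure each minute, but removal of the
device leaves gaps: minutes with no heart-rate reading are non-wear, and
summarising the remaining data as-is implicitly treats the missing minutes
as zero activity, biasing daily step counts, total daily energy expenditure
(TDEE) and time-in-intensity estimates downward. `wearimpute` is for
researchers who collect such data in free-living studies and need defensible
physical-activity summaries despite non-wear.

## What it implements

**Wear-time scaling with validity screening.** Observed totals are
extrapolated to the full interval by dividing by the wear fraction,
hierarchically:

1. an hour with ≥ 5 worn minutes scales its total by `(worn / 60)⁻¹`,
   otherwise the hour is removed;
2. a day with ≥ 18 valid hours scales the sum of its scaled hours by
   `(valid hours / 24)⁻¹`, otherwise the day is removed;
3. a 14-day period with ≥ 4 valid days, at least one of them a weekend day,
   reports the mean of its valid days, otherwise the period is removed.

**Comparator imputers**, filling gaps at the minute level: overall and
individual mean imputation; multiple imputation by bootstrapped predictive
mean matching (m = 5 overall with age/sex/weekday covariates, m = 7
individual with weekday/hour covariates); iterative random-forest
imputation (100 trees, √p variables per split, ≤ 5 iterations); and Kalman
smoothing under a maximum-likelihood local-level structural model.

**Intensity classification by heart-rate reserve (HRR):**

```
%HRR = (HR − HRrest) / (HRmax − HRrest) × 100
```

with HRmax = 208 − 0.7·age (Tanaka), HRrest = 1.08 × sleeping HR, and
sleeping HR the lowest mean of 20 consecutive still night minutes. Minutes
classify as sedentary (< 20 %HRR), light [20, 40), moderate [40, 60) or
vigorous (≥ 60).

**Missingness simulators and evaluation statistics**: random insertion of
non-wear periods (uniform starts, lengths uniform on 1–120 min, overlaps
unioned), ten incremental-missingness windows (0–10 … 90–100 periods), RMSE,
paired TOST equivalence against ±10% of the criterion mean, two-way
mixed-effects absolute-agreement ICC, and autocorrelation profiles — plus
`run_study1` / `run_study2` pipelines that compare every method against
held-back truth on a synthetic cohort.

**A synthetic cohort generator** produces complete 14-day minute-grid
participants with circadian structure (sleep window, sedentary baseline,
Poisson activity bouts, HR coupled to cadence, AR(1) HR noise) so that every
experiment runs without access to any trial data.

## Worked example

```python
import wearimpute as wi

series = wi.generate_participant(wi.calibrated_profile(), seed=7)
plan = wi.draw_plan(40, len(series), seed=11)
masked, inserted = wi.apply_plan(series, plan)
print(f"inserted missingness: {100*inserted.mean():.2f}% of minutes")

true = wi.removal_summaries(series, "steps")
removal = wi.removal_summaries(masked, "steps")
scaled = wi.nohow_summaries(masked, "steps")
print(f"true 14-day mean steps/day:     {true.period_value:8.1f}")
print(f"removal (no adjustment):        {removal.period_value:8.1f}")
print(f"wear-time scaled:               {scaled.period_value:8.1f}")

kalman = wi.impute_kalman(masked, seed=3, channels=("steps",))
k = wi.removal_summaries(kalman.completed, "steps")
print(f"kalman-imputed:                 {k.period_value:8.1f}")
```

prints

```
inserted missingness: 12.26% of minutes
true 14-day mean steps/day:      11282.0
removal (no adjustment):          9740.0
wear-time scaled:                11372.9
kalman-imputed:                  11417.0
```

The 40 inserted non-wear periods blank about 12% of the fortnight. Ignoring
them ("removal") undercounts daily steps by ~1,540 steps/day; wear-time
scaling and Kalman imputation both land within ~1% of the truth.

A command-line interface mirrors the library (`wearimpute simulate-cohort`,
`insert-missingness`, `impute`, `hrr`, `summarize`, `study1`, `study2`,
`run`); see `wearimpute --help`.

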