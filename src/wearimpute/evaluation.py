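"""Evaluation statistics and the two simulation-study pipelines.

Methods are compared with the held-back true data through:

* RMSE, √(Σ(ŷᵢ − yᵢ)²/n), pooled over participant-hours at the hourly
  level, participant-days at the daily level, and participants at the
  14-day level;
* paired equivalence (TOST) tests: a method is equivalent to truth when the
  90% confidence interval of the mean difference lies within ±10% of the
  criterion (true) mean — operationalised as two one-sided paired t-tests at
  α = 0.05;
* two-way mixed-effects, absolute-agreement, single-measure intraclass
  correlation (ICC) for the wear-time-requirement curves;
* sample autocorrelation profiles of the minute-level channels.

Simulation study 1 inserts 40 random missing periods per participant and
compares every method at every level; study 2 sweeps ten windows of
increasing missingness (0–10 up to 90–100 periods) for the individual-
centred methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import hrr_intensity, imputers, missingness, nohow_scaling
from .datamodel import CATEGORIES, METRICS, MetricName, ParticipantSeries

DEFAULT_MARGIN_FRACTION = 0.10
DEFAULT_ALPHA = 0.05
ICC_THRESHOLD = 0.9
STUDY2_METHODS = ("nohow", "kalman", "individual_mi")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def rmse(predicted: np.ndarray, true: np.ndarray) -> float:
    """Root mean squared error between paired sequences."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or predicted.size < 1:
        raise ValueError("predicted and true must be equal-length, non-empty")
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


@dataclass(frozen=True)
class EquivalenceOutcome:
    """Result of a paired TOST equivalence test against ±margin·mean(true)."""

    n: int
    mean_true: float
    mean_imputed: float
    mean_difference: float
    bound: float
    p_lower: float
    p_upper: float
    equivalent: bool


def equivalence_test(
    imputed: np.ndarray,
    true: np.ndarray,
    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> EquivalenceOutcome:
    """Paired two-one-sided-tests equivalence against ±margin·mean(true).

    ``p_upper`` tests H0: mean(d) ≥ +bound and ``p_lower`` tests
    H0: mean(d) ≤ −bound for d = imputed − true; equivalence is declared when
    both are rejected, which is identical to the (1 − 2α) confidence interval
    of the mean difference lying inside ±bound. A zero-variance difference is
    judged directly against the bound with p reported as 0 (or 1).
    """
    imputed = np.asarray(imputed, dtype=float)
    true = np.asarray(true, dtype=float)
    if imputed.shape != true.shape:
        raise ValueError("paired samples must have equal length")
    n = imputed.size
    if n < 2:
        raise ValueError("equivalence testing requires n >= 2 pairs")
    d = imputed - true
    mean_d = float(np.mean(d))
    bound = float(margin_fraction * np.mean(true))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        inside = abs(mean_d) < abs(bound)
        p = 0.0 if inside else 1.0
        return EquivalenceOutcome(
            n, float(np.mean(true)), float(np.mean(imputed)), mean_d, bound, p, p, inside
        )
    se = sd / np.sqrt(n)
    df = n - 1
    t_upper = (mean_d - bound) / se
    t_lower = (mean_d + bound) / se
    p_upper = float(stats.t.cdf(t_upper, df))
    p_lower = float(stats.t.sf(t_lower, df))
    return EquivalenceOutcome(
        n,
        float(np.mean(true)),
        float(np.mean(imputed)),
        mean_d,
        bound,
        p_lower,
        p_upper,
        bool(max(p_lower, p_upper) < alpha),
    )


@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC."""

    icc: float
    n_subjects: int
    k_raters: int
    model: str = "two-way mixed, absolute agreement, single measure"


def icc_agreement(ratings: np.ndarray) -> ICCResult:
    """ICC(A,1) from the two-way ANOVA decomposition of an n×k rating table.

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)) with MSR, MSC
    and MSE the row (subject), column (rater) and residual mean squares.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be an n_subjects × k_raters table")
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(ratings).any():
        raise ValueError("ratings table must be complete")
    grand = ratings.mean()
    sst = float(np.sum((ratings - grand) ** 2))
    if sst == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return ICCResult(float(icc), n, k)


def acf_profile(series: ParticipantSeries, channel: str, max_lag: int = 10080) -> np.ndarray:
    """Sample autocorrelation of one channel at lags 0…max_lag.

    Requires a complete channel (no missing minutes); lag 0 is included (and
    equals 1) but carries no information.
    """
    from statsmodels.tsa.stattools import acf

    x = series.channel(channel)
    if np.isnan(x).any():
        raise ValueError("autocorrelation requires a complete channel")
    return np.asarray(acf(x, nlags=max_lag, fft=True))


def cohort_acf(
    cohort: list[ParticipantSeries], channel: str, max_lag: int = 10080
) -> pd.DataFrame:
    """Per-lag mean ± SD of the autocorrelation across a cohort."""
    profiles = np.stack([acf_profile(s, channel, max_lag) for s in cohort])
    return pd.DataFrame(
        {"lag": np.arange(max_lag + 1), "mean": profiles.mean(axis=0), "sd": profiles.std(axis=0)}
    )


# ---------------------------------------------------------------------------
# wear-time-requirement ICC curves
# ---------------------------------------------------------------------------

def wear_requirement_curve(
    cohort: list[ParticipantSeries],
    level: str,
    seed: int | np.random.SeedSequence | None = None,
    metric: MetricName = "steps",
) -> pd.DataFrame:
    """ICC between incrementally deleted data and the truth at one level.

    hour: w = 0…55 random minutes are deleted from every clock hour and the
    remaining total is divided by the retained wear proportion before
    computing the ICC against the true hourly totals (across all
    participant-hours). day: whole hours are deleted with no scaling, against
    true daily totals. period: whole days are deleted and the mean of the
    remainder is compared with the true 14-day mean across participants.

    Returns a table (units_deleted, units_retained, icc).
    """
    rng = np.random.default_rng(seed)
    v_all = [np.nan_to_num(nohow_scaling.metric_values(s, metric), nan=0.0) for s in cohort]
    rows = []
    if level == "hour":
        blocks = np.vstack([v.reshape(-1, 60) for v in v_all])  # all participant-hours
        true = blocks.sum(axis=1)
        for w in range(0, 56):
            keep = 60 - w
            scaled = np.empty(len(blocks))
            for i in range(len(blocks)):
                idx = rng.choice(60, size=keep, replace=False)
                scaled[i] = blocks[i, idx].sum() / (keep / 60.0)
            rows.append((w, keep, icc_agreement(np.column_stack([true, scaled])).icc))
    elif level == "day":
        hours = np.vstack([v.reshape(-1, 60).sum(axis=1).reshape(-1, 24) for v in v_all])
        true = hours.sum(axis=1)
        for w in range(0, 24):
            keep = 24 - w
            partial = np.empty(len(hours))
            for i in range(len(hours)):
                idx = rng.choice(24, size=keep, replace=False)
                partial[i] = hours[i, idx].sum()  # no scaling at the daily level
            rows.append((w, keep, icc_agreement(np.column_stack([true, partial])).icc))
    elif level == "period":
        days = np.vstack(
            [v.reshape(-1, 1440).sum(axis=1).reshape(1, -1) for v in v_all]
        )  # participants × days
        n_days = days.shape[1]
        true = days.mean(axis=1)
        for w in range(0, n_days):
            keep = n_days - w
            partial = np.empty(len(days))
            for i in range(len(days)):
                idx = rng.choice(n_days, size=keep, replace=False)
                partial[i] = days[i, idx].mean()
            rows.append((w, keep, icc_agreement(np.column_stack([true, partial])).icc))
    else:
        raise ValueError(f"unknown level {level!r}")
    return pd.DataFrame(rows, columns=["units_deleted", "units_retained", "icc"])


def minimum_retained(curve: pd.DataFrame, threshold: float = ICC_THRESHOLD) -> int | None:
    """Smallest retained amount whose ICC still meets the threshold."""
    ok = curve[curve["icc"] >= threshold]
    return int(ok["units_retained"].min()) if len(ok) else None


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------

def _needed_channels(metrics: tuple[str, ...]) -> tuple[str, ...]:
    channels = []
    if "steps" in metrics:
        channels.append("steps")
    if any(m in CATEGORIES for m in metrics):
        channels.append("heart_rate")
    if "tdee" in metrics:
        channels.append("kcal")
    return tuple(channels)


def _method_summaries(
    method: str,
    masked: ParticipantSeries,
    metrics: tuple[str, ...],
    profile: hrr_intensity.IntensityProfile,
    cohort: list[ParticipantSeries] | None,
    seed: np.random.SeedSequence | int | None,
) -> dict[str, nohow_scaling.LevelSummaries]:
    """Hour/day/period summaries for one method on one masked series.

    Multiple-imputation methods average the summaries of the m completed
    datasets; scaling/removal act on the masked series directly.
    """
    if method == "removal":
        return {m: nohow_scaling.removal_summaries(masked, m, profile) for m in metrics}
    if method == "nohow":
        return {m: nohow_scaling.nohow_summaries(masked, m, profile) for m in metrics}
    result = imputers.run_method(
        method, masked, cohort=cohort, seed=seed, channels=_needed_channels(metrics)
    )
    out: dict[str, nohow_scaling.LevelSummaries] = {}
    for m in metrics:
        per_ds = [nohow_scaling.removal_summaries(ds, m, profile) for ds in result.datasets]
        first = per_ds[0]
        out[m] = nohow_scaling.LevelSummaries(
            m,
            np.mean([s.hour_values for s in per_ds], axis=0),
            first.hour_valid,
            np.mean([s.day_values for s in per_ds], axis=0),
            first.day_valid,
            float(np.mean([s.period_value for s in per_ds])),
            True,
        )
    return out


def run_study1(
    cohort: list[ParticipantSeries],
    methods: tuple[str, ...] = imputers.METHOD_NAMES,
    n_periods: int = missingness.STUDY1_N_PERIODS,
    seed: int | None = None,
    metrics: tuple[str, ...] = METRICS,
    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Insert 40-period missingness once per participant and compare methods.

    Every method sees the same masked series. Returns one row per
    method × metric × level with pooled RMSE, means, the equivalence bound
    and TOST p-values. Units the wear-time scaling marks invalid are excluded
    pairwise for that method only.
    """
    root = np.random.SeedSequence(seed)
    plan_seeds = root.spawn(len(cohort))
    method_seeds = {m: root.spawn(len(cohort)) for m in methods}

    masked_all: list[ParticipantSeries] = []
    profiles: list[hrr_intensity.IntensityProfile] = []
    for series, ss in zip(cohort, plan_seeds):
        plan = missingness.draw_plan(n_periods, len(series), seed=ss)
        masked, _ = missingness.apply_plan(series, plan)
        masked_all.append(masked)
        profiles.append(hrr_intensity.build_profile(series))

    true_summaries = [
        {m: nohow_scaling.removal_summaries(s, m, p) for m in metrics}
        for s, p in zip(cohort, profiles)
    ]

    pooled: dict[tuple[str, str, str], tuple[list, list]] = {
        (method, m, lvl): ([], []) for method in methods for m in metrics for lvl in ("hour", "day", "period")
    }
    for i, masked in enumerate(masked_all):
        for method in methods:
            summaries = _method_summaries(
                method, masked, metrics, profiles[i], masked_all, method_seeds[method][i]
            )
            for m in metrics:
                for lvl in ("hour", "day", "period"):
                    pred, valid = summaries[m].at(lvl)
                    true, _ = true_summaries[i][m].at(lvl)
                    keep = np.asarray(valid, dtype=bool)
                    p_list, t_list = pooled[(method, m, lvl)]
                    p_list.extend(np.asarray(pred)[keep])
                    t_list.extend(np.asarray(true)[keep])

    rows = []
    for (method, m, lvl), (pred, true) in pooled.items():
        pred = np.asarray(pred, dtype=float)
        true = np.asarray(true, dtype=float)
        eq = equivalence_test(pred, true, margin_fraction, alpha)
        rows.append(
            {
                "method": method,
                "metric": m,
                "level": lvl,
                "n": eq.n,
                "true_mean": eq.mean_true,
                "imputed_mean": eq.mean_imputed,
                "mean_diff": eq.mean_difference,
                "rmse": rmse(pred, true),
                "bound": eq.bound,
                "p_lower": eq.p_lower,
                "p_upper": eq.p_upper,
                "equivalent": eq.equivalent,
            }
        )
    return pd.DataFrame(rows)


def run_study2(
    cohort: list[ParticipantSeries],
    methods: tuple[str, ...] = STUDY2_METHODS,
    windows: tuple[int, ...] = tuple(range(1, 11)),
    sims_per_window: int = 20,
    seed: int | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Sweep ten incremental-missingness windows for the individual methods.

    For each window and simulation, the number of inserted periods is drawn
    from the window's range, the series is masked, and each method's 14-day
    period value is recorded against the truth. Returns one row per
    participant × window × simulation × method × metric; aggregate with
    :func:`study2_window_rmse`.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for i, series in enumerate(cohort):
        profile = hrr_intensity.build_profile(series)
        true_summ = {m: nohow_scaling.removal_summaries(series, m, profile) for m in metrics}
        for w in windows:
            for sim in range(sims_per_window):
                # one deterministic seed branch per (participant, window, sim)
                draw_ss, plan_ss, *method_ss = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(1, i, w, sim)
                ).spawn(2 + len(methods))
                count = missingness.study2_period_count(w, draw_ss)
                plan = missingness.draw_plan(count, len(series), seed=plan_ss)
                masked, inserted = missingness.apply_plan(series, plan)
                for method, ss in zip(methods, method_ss):
                    summaries = _method_summaries(method, masked, metrics, profile, [masked], ss)
                    for m in metrics:
                        rows.append(
                            {
                                "participant_id": series.participant_id,
                                "window": w,
                                "sim": sim,
                                "method": method,
                                "metric": m,
                                "inserted_fraction": float(inserted.mean()),
                                "true_value": true_summ[m].period_value,
                                "value": summaries[m].period_value,
                                "valid": bool(summaries[m].period_valid),
                            }
                        )
    return pd.DataFrame(rows)


def study2_window_rmse(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-window RMSE of the 14-day value over simulations.

    Invalid (screened-out) period values are excluded pairwise.
    """
    ok = table[table["valid"] & table["value"].notna()]
    grouped = ok.groupby(["method", "metric", "window", "participant_id"])
    out = grouped.apply(
        lambda g: rmse(g["value"].to_numpy(), g["true_value"].to_numpy()),
        include_groups=False,
    ).rename("rmse")
    return out.reset_index()


def window_trend_sign_test(window_rmse: pd.DataFrame, low: int = 1, high: int = 10) -> pd.DataFrame:
    """One-sided paired sign test that RMSE grows from a low to a high window.

    Pairs participants' RMSE in the two windows per method × metric and tests
    H0: increases are no more likely than decreases (binomial, p = 1/2).
    """
    rows = []
    for (method, metric), grp in window_rmse.groupby(["method", "metric"]):
        a = grp[grp["window"] == low].set_index("participant_id")["rmse"]
        b = grp[grp["window"] == high].set_index("participant_id")["rmse"]
        common = a.index.intersection(b.index)
        diff = (b[common] - a[common]).to_numpy()
        diff = diff[diff != 0]
        n_pos = int((diff > 0).sum())
        p = float(stats.binomtest(n_pos, len(diff), 0.5, alternative="greater").pvalue) if len(diff) else 1.0
        rows.append(
            {"method": method, "metric": metric, "n_pairs": len(diff), "n_increased": n_pos, "p_value": p}
        )
    return pd.DataFrame(rows)
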