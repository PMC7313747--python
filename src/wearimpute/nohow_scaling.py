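"""Wear-time scaling of activity summaries (the NoHoW algorithm).

The algorithm extrapolates partially observed intervals to full intervals by
dividing observed totals by the observed wear fraction, subject to minimum
wear requirements at each aggregation level:

1. hour: if fewer than 5 worn minutes, the hour is invalid; otherwise the
   hourly total is divided by (worn minutes / 60);
2. day: if fewer than 18 valid hours, the day is invalid; otherwise the sum
   of the scaled hourly totals is divided by (valid hours / 24);
3. 14-day period: invalid unless at least 4 valid days including at least
   one weekend day (Saturday/Sunday); otherwise the mean of valid scaled
   daily totals.

Scaling applies to accumulable metrics only (steps, kcal, and per-minute
intensity-category indicators, which scale to minutes in category); heart
rate itself is never scaled. The "Removal" comparator summarises the
observed minutes with no scaling and no validity screening, implicitly
treating missing minutes as zero activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np

from . import hrr_intensity
from .datamodel import (
    CATEGORIES,
    DAYS_PER_PERIOD,
    MINUTES_PER_DAY,
    MetricName,
    ParticipantSeries,
)

MIN_MINUTES_PER_HOUR = 5
MIN_HOURS_PER_DAY = 18
MIN_DAYS_PER_PERIOD = 4
MIN_WEEKEND_DAYS = 1


@dataclass(frozen=True)
class ScaledSummary:
    """One scaled (or plain) summary value with its validity flag.

    ``value`` is NaN whenever ``valid`` is False — an invalid unit carries no
    value, never zero. ``n_units_used`` counts worn minutes for an hour,
    valid hours for a day and valid days for a period.
    """

    level: str
    metric: str
    value: float
    valid: bool
    wear_fraction: float
    n_units_used: int
    date: _date | None = None


def metric_values(
    series: ParticipantSeries,
    metric: MetricName,
    profile: hrr_intensity.IntensityProfile | None = None,
) -> np.ndarray:
    """Per-minute contributions of a metric (NaN on non-worn minutes).

    steps → steps/min; tdee → kcal/min; category metrics → the 0/1
    per-minute indicator of that intensity category (so summed/scaled values
    are minutes in category).
    """
    if metric == "steps":
        return series.channel("steps")
    if metric == "tdee":
        return series.channel("kcal")
    if metric in CATEGORIES:
        if profile is None:
            profile = hrr_intensity.build_profile(series)
        return hrr_intensity.category_indicators(series, profile)[metric]
    raise ValueError(f"unknown metric {metric!r}")


def scale_hour(values: np.ndarray, metric: MetricName = "steps") -> ScaledSummary:
    """Scale one clock hour's per-minute metric values (NaN = not worn)."""
    values = np.asarray(values, dtype=float)
    if len(values) > 60:
        raise ValueError("an hour holds at most 60 minute values")
    worn = int(np.sum(~np.isnan(values)))
    if worn < MIN_MINUTES_PER_HOUR:
        return ScaledSummary("hour", metric, float("nan"), False, worn / 60.0, worn)
    total = float(np.nansum(values))
    return ScaledSummary("hour", metric, total / (worn / 60.0), True, worn / 60.0, worn)


def scale_day(hours: list[ScaledSummary], metric: MetricName = "steps") -> ScaledSummary:
    """Combine the 24 scaled hourly summaries of one calendar date."""
    if len(hours) != 24:
        raise ValueError("a day holds exactly 24 hourly summaries")
    valid = [h for h in hours if h.valid]
    k = len(valid)
    if k < MIN_HOURS_PER_DAY:
        return ScaledSummary("day", metric, float("nan"), False, k / 24.0, k)
    total = float(sum(h.value for h in valid))
    return ScaledSummary("day", metric, total / (k / 24.0), True, k / 24.0, k)


def summarize_period(days: list[ScaledSummary], metric: MetricName = "steps") -> ScaledSummary:
    """Average the valid days of one 14-day period, with weekend screening.

    Each day summary must carry its calendar ``date`` so weekend days
    (Saturday/Sunday) can be recognised.
    """
    if len(days) != DAYS_PER_PERIOD:
        raise ValueError(f"a period holds exactly {DAYS_PER_PERIOD} daily summaries")
    valid = [d for d in days if d.valid]
    k = len(valid)
    weekend = sum(1 for d in valid if d.date is not None and d.date.weekday() >= 5)
    if k < MIN_DAYS_PER_PERIOD or weekend < MIN_WEEKEND_DAYS:
        return ScaledSummary("period", metric, float("nan"), False, k / DAYS_PER_PERIOD, k)
    value = float(np.mean([d.value for d in valid]))
    return ScaledSummary("period", metric, value, True, k / DAYS_PER_PERIOD, k)


@dataclass(frozen=True)
class LevelSummaries:
    """Hour/day/period summary values for one series and metric.

    ``hour_values`` has one entry per clock hour of the series (NaN where
    invalid), ``day_values`` one per calendar day; ``period_value`` is the
    14-day summary. The matching ``*_valid`` arrays flag usable units (always
    all-True for the Removal comparator).
    """

    metric: str
    hour_values: np.ndarray
    hour_valid: np.ndarray
    day_values: np.ndarray
    day_valid: np.ndarray
    period_value: float
    period_valid: bool

    def at(self, level: str):
        if level == "hour":
            return self.hour_values, self.hour_valid
        if level == "day":
            return self.day_values, self.day_valid
        if level == "period":
            return np.array([self.period_value]), np.array([self.period_valid])
        raise ValueError(f"unknown level {level!r}")


def _day_weekend_flags(series: ParticipantSeries, n_days: int) -> np.ndarray:
    dates = series.timestamps[:: MINUTES_PER_DAY]
    return np.asarray(dates.weekday >= 5)[:n_days]


def nohow_summaries(
    series: ParticipantSeries,
    metric: MetricName,
    profile: hrr_intensity.IntensityProfile | None = None,
) -> LevelSummaries:
    """Run the full scaling cascade (hour → day → 14-day period) on a series."""
    v = metric_values(series, metric, profile)
    n_days = len(v) // MINUTES_PER_DAY
    if n_days * MINUTES_PER_DAY != len(v):
        raise ValueError("series must span whole days")
    V = v[: n_days * MINUTES_PER_DAY].reshape(n_days * 24, 60)
    worn = (~np.isnan(V)).sum(axis=1)
    hour_valid = worn >= MIN_MINUTES_PER_HOUR
    with np.errstate(invalid="ignore", divide="ignore"):
        hour_values = np.where(hour_valid, np.nansum(V, axis=1) / (worn / 60.0), np.nan)

    H = hour_values.reshape(n_days, 24)
    HV = hour_valid.reshape(n_days, 24)
    k = HV.sum(axis=1)
    day_valid = k >= MIN_HOURS_PER_DAY
    day_totals = np.nansum(np.where(HV, H, np.nan), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        day_values = np.where(day_valid, day_totals / (k / 24.0), np.nan)

    weekend = _day_weekend_flags(series, n_days)
    n_valid_days = int(day_valid.sum())
    period_valid = bool(
        n_valid_days >= MIN_DAYS_PER_PERIOD and (day_valid & weekend).sum() >= MIN_WEEKEND_DAYS
    )
    period_value = float(np.mean(day_values[day_valid])) if period_valid else float("nan")
    return LevelSummaries(
        metric, hour_values, hour_valid, day_values, day_valid, period_value, period_valid
    )


def removal_summaries(
    series: ParticipantSeries,
    metric: MetricName,
    profile: hrr_intensity.IntensityProfile | None = None,
) -> LevelSummaries:
    """Plain unscaled summaries: missing minutes contribute zero, no screening."""
    v = metric_values(series, metric, profile)
    n_days = len(v) // MINUTES_PER_DAY
    V = np.nan_to_num(v[: n_days * MINUTES_PER_DAY], nan=0.0).reshape(n_days * 24, 60)
    hour_values = V.sum(axis=1)
    day_values = hour_values.reshape(n_days, 24).sum(axis=1)
    period_value = float(np.mean(day_values))
    ones_h = np.ones(n_days * 24, dtype=bool)
    ones_d = np.ones(n_days, dtype=bool)
    return LevelSummaries(metric, hour_values, ones_h, day_values, ones_d, period_value, True)


def summarize_removal(
    series: ParticipantSeries,
    metric: MetricName,
    level: str,
    profile: hrr_intensity.IntensityProfile | None = None,
):
    """Removal-comparator values at one level (array for hour/day, float for period)."""
    summaries = removal_summaries(series, metric, profile)
    if level == "period":
        return summaries.period_value
    return summaries.at(level)[0]
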