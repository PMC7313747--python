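"""Heart-rate-reserve (HRR) relative-intensity classification.

Each worn minute is placed in one of four intensity categories from the
position of its heart rate within the participant's heart-rate reserve:

    %HRR = (HR − HRrest) / (HRmax − HRrest) × 100

with HRmax from the Tanaka age equation (208 − 0.7·age) and HRrest taken as
an 8% increase over sleeping heart rate. Sleeping heart rate is the minimum,
over all nights, of the mean of 20 consecutive night minutes (00:00–07:59)
in which fewer than 5 steps/min were taken and heart rate was recorded.

Cut points: sedentary < 20% HRR, light [20, 40), moderate [40, 60),
vigorous ≥ 60. The printed boundaries are adopted half-open on the left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CATEGORIES, MINUTES_PER_DAY, ParticipantSeries

SLEEP_WINDOW_MINUTES = 20
NIGHT_END_HOUR = 8  # windows must lie within 00:00–07:59
LOW_STEP_THRESHOLD = 5  # steps/min strictly below this counts as "still"
REST_OVER_SLEEP = 1.08  # resting HR ≈ sleeping HR + 8%

#: Lower edges of (sedentary, light, moderate, vigorous) in %HRR.
CATEGORY_EDGES = (20.0, 40.0, 60.0)


class NoSleepWindowError(ValueError):
    """No qualifying 20-minute low-movement night window exists in the series."""


@dataclass(frozen=True)
class IntensityProfile:
    """Per-participant heart-rate anchors for %HRR classification."""

    hr_max: float
    hr_sleep: float
    hr_rest: float
    age: float

    def __post_init__(self) -> None:
        if not (0 < self.hr_sleep and 0 < self.hr_rest < self.hr_max):
            raise ValueError(f"inconsistent heart-rate anchors: {self}")
        if abs(self.hr_rest - REST_OVER_SLEEP * self.hr_sleep) > 1e-9:
            raise ValueError("hr_rest must equal 1.08 × hr_sleep")


def max_heart_rate(age: float) -> float:
    """Age-predicted maximum heart rate (Tanaka equation, 208 − 0.7·age)."""
    if not 18 <= age <= 100:
        raise ValueError(f"age {age} outside the supported adult range [18, 100]")
    return 208.0 - 0.7 * age


def resting_heart_rate(hr_sleep: float) -> float:
    """Resting heart rate approximated as an 8% increase over sleeping HR."""
    if hr_sleep <= 0:
        raise ValueError("sleeping heart rate must be positive")
    return REST_OVER_SLEEP * hr_sleep


def sleeping_heart_rate(series: ParticipantSeries) -> float:
    """Minimum mean HR over 20 consecutive still night minutes, all nights pooled.

    A window qualifies when all 20 minutes fall between 00:00 and 07:59 of one
    calendar date, every minute has heart rate present, and every minute has
    steps < 5. Windows containing any missing HR minute are skipped.
    """
    data = series.data
    ts = series.timestamps
    hr = data["heart_rate"].to_numpy(dtype=float)
    steps = data["steps"].to_numpy(dtype=float)
    night = ts.hour < NIGHT_END_HOUR
    ok = night & ~np.isnan(hr) & ~np.isnan(steps) & (steps < LOW_STEP_THRESHOLD)
    # windows may not cross a night boundary: group by calendar date
    best = np.inf
    day = ts.normalize()
    frame = pd.DataFrame({"hr": hr, "ok": ok})
    for _, grp in frame[night].groupby(day[night]):
        v = np.where(grp["ok"].to_numpy(), grp["hr"].to_numpy(), np.nan)
        if len(v) < SLEEP_WINDOW_MINUTES:
            continue
        means = (
            pd.Series(v).rolling(SLEEP_WINDOW_MINUTES).mean().to_numpy()
        )  # NaN unless the whole window qualifies
        if not np.all(np.isnan(means)):
            best = min(best, float(np.nanmin(means)))
    if not np.isfinite(best):
        raise NoSleepWindowError(
            "no 20-minute window between 00:00 and 08:00 with steps < 5 and heart rate "
            "present; supply a resting heart rate explicitly for this participant"
        )
    return best


def build_profile(series: ParticipantSeries) -> IntensityProfile:
    """Derive the participant's intensity anchors from their own series."""
    hr_sleep = sleeping_heart_rate(series)
    return IntensityProfile(
        hr_max=max_heart_rate(series.age),
        hr_sleep=hr_sleep,
        hr_rest=resting_heart_rate(hr_sleep),
        age=series.age,
    )


def percent_hrr(hr: float | np.ndarray, profile: IntensityProfile) -> float | np.ndarray:
    """Heart rate expressed as a percentage of heart-rate reserve.

    May be negative (HR below rest) or exceed 100 (HR above predicted max).
    """
    return (hr - profile.hr_rest) / (profile.hr_max - profile.hr_rest) * 100.0


def classify_minute(pct: float) -> str:
    """Intensity category for one minute's %HRR value."""
    if not np.isfinite(pct):
        raise ValueError("non-finite %HRR value")
    return CATEGORIES[int(np.searchsorted(CATEGORY_EDGES, pct, side="right"))]


def classify_series(series: ParticipantSeries, profile: IntensityProfile) -> np.ndarray:
    """Per-minute category index (0=sedentary … 3=vigorous), −1 where non-worn."""
    hr = series.channel("heart_rate")
    pct = percent_hrr(hr, profile)
    idx = np.searchsorted(CATEGORY_EDGES, pct, side="right")
    return np.where(np.isnan(hr), -1, idx).astype(int)


def category_indicators(series: ParticipantSeries, profile: IntensityProfile) -> dict[str, np.ndarray]:
    """Per-minute 0/1 indicator per category; NaN on non-worn minutes."""
    idx = classify_series(series, profile)
    out: dict[str, np.ndarray] = {}
    for k, cat in enumerate(CATEGORIES):
        ind = (idx == k).astype(float)
        ind[idx < 0] = np.nan
        out[cat] = ind
    return out


def minutes_by_category(series: ParticipantSeries, profile: IntensityProfile) -> pd.DataFrame:
    """Worn minutes per calendar date in each intensity category.

    Missing minutes belong to no category, so a day's counts sum to the number
    of worn minutes that day (1440 for a fully worn day).
    """
    idx = classify_series(series, profile)
    day = series.timestamps.normalize()
    rows = []
    for date, grp in pd.Series(idx).groupby(day):
        counts = {cat: int(np.sum(grp.to_numpy() == k)) for k, cat in enumerate(CATEGORIES)}
        rows.append({"date": date.date(), **counts})
    out = pd.DataFrame(rows)
    assert (out[list(CATEGORIES)].sum(axis=1) <= MINUTES_PER_DAY).all()
    return out
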