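"""Core minute-grid time-series types and CSV round-tripping.

The universal input of the package is a per-participant, minute-resolution
multichannel series: step counts, heart rate (bpm) and energy expenditure
(kcal/min), on a complete one-minute grid. Non-wear is encoded as an absent
heart-rate value; whenever heart rate is absent for a minute, the steps and
energy channels for that minute are treated as missing too, since the device
was off the wrist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, NamedTuple

import numpy as np
import pandas as pd

#: Channels stored per minute, in file order.
CHANNELS = ("steps", "heart_rate", "kcal")

#: The closed set of physical-activity summary metrics.
METRICS = ("steps", "tdee", "sedentary", "light", "moderate", "vigorous")

#: Metrics that accumulate over minutes (summable); heart rate itself is not a metric.
ACCUMULABLE_METRICS = METRICS  # steps & kcal sum; category metrics sum minute indicators

#: Intensity categories, ordered from least to most intense.
CATEGORIES = ("sedentary", "light", "moderate", "vigorous")

MINUTES_PER_DAY = 1440
DAYS_PER_PERIOD = 14
MINUTES_PER_PERIOD = DAYS_PER_PERIOD * MINUTES_PER_DAY  # 20160

HR_LOW, HR_HIGH = 25.0, 250.0  # physiological plausibility bounds, open interval

CSV_HEADER = ["participant_id", "age", "sex", "timestamp", "steps", "heart_rate", "kcal"]

MetricName = Literal["steps", "tdee", "sedentary", "light", "moderate", "vigorous"]
Level = Literal["hour", "day", "period"]


class MinuteRecord(NamedTuple):
    """One minute of data; ``None`` encodes an absent (non-worn) channel."""

    timestamp: pd.Timestamp
    steps: float | None
    heart_rate: float | None
    kcal: float | None


class SeriesValidationError(ValueError):
    """Raised when a series violates the minute-grid or channel invariants."""


def minute_grid(n_minutes: int, start: str | pd.Timestamp = "2020-01-06") -> pd.DatetimeIndex:
    """A complete 1-minute grid of ``n_minutes`` starting at midnight of ``start``.

    The default start is a Monday so that a 14-day series contains exactly
    four weekend days (two Saturdays, two Sundays).
    """
    start = pd.Timestamp(start).normalize()
    return pd.date_range(start, periods=n_minutes, freq="min")


@dataclass
class ParticipantSeries:
    """A participant's minute-grid multichannel activity series.

    ``data`` holds one row per minute with columns ``timestamp`` (naive local
    time), ``steps``, ``heart_rate`` and ``kcal``; missing channel values are
    NaN. The grid is complete: consecutive timestamps differ by exactly one
    minute and the first row is a midnight.
    """

    participant_id: str
    age: float
    sex: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_series(self)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def worn(self) -> np.ndarray:
        """Boolean per-minute wear mask (worn ⇔ heart rate present)."""
        return self.data["heart_rate"].notna().to_numpy()

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["timestamp"])

    def channel(self, name: str) -> np.ndarray:
        """Per-minute values of one channel as a float array (NaN = missing)."""
        return self.data[name].to_numpy(dtype=float)

    @property
    def records(self) -> Iterator[MinuteRecord]:
        for row in self.data.itertuples(index=False):
            yield MinuteRecord(
                row.timestamp,
                None if pd.isna(row.steps) else float(row.steps),
                None if pd.isna(row.heart_rate) else float(row.heart_rate),
                None if pd.isna(row.kcal) else float(row.kcal),
            )

    def replace_data(self, data: pd.DataFrame) -> "ParticipantSeries":
        """A new series with the same identity but different channel data."""
        return ParticipantSeries(self.participant_id, self.age, self.sex, data)

    def copy(self) -> "ParticipantSeries":
        return self.replace_data(self.data.copy())

    def equals(self, other: "ParticipantSeries") -> bool:
        return (
            self.participant_id == other.participant_id
            and self.age == other.age
            and self.sex == other.sex
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


def build_series(
    participant_id: str,
    age: float,
    sex: str,
    steps: np.ndarray,
    heart_rate: np.ndarray,
    kcal: np.ndarray,
    start: str | pd.Timestamp = "2020-01-06",
) -> ParticipantSeries:
    """Assemble a series from per-minute channel arrays on a fresh grid."""
    steps = np.asarray(steps, dtype=float)
    n = len(steps)
    data = pd.DataFrame(
        {
            "timestamp": minute_grid(n, start),
            "steps": steps,
            "heart_rate": np.asarray(heart_rate, dtype=float),
            "kcal": np.asarray(kcal, dtype=float),
        }
    )
    return ParticipantSeries(participant_id, float(age), sex, harmonize_missing(data))


def harmonize_missing(data: pd.DataFrame) -> pd.DataFrame:
    """Blank steps and kcal wherever heart rate is absent (non-wear rule)."""
    off = data["heart_rate"].isna().to_numpy()
    if off.any():
        data = data.copy()
        data.loc[off, ["steps", "kcal"]] = np.nan
    return data


def validate_series(series: ParticipantSeries) -> None:
    data = series.data
    missing_cols = [c for c in ("timestamp", *CHANNELS) if c not in data.columns]
    if missing_cols:
        raise SeriesValidationError(f"series data lacks columns {missing_cols}")
    if len(data) == 0:
        raise SeriesValidationError("series has no rows")
    ts = pd.DatetimeIndex(data["timestamp"])
    if ts[0] != ts[0].normalize():
        raise SeriesValidationError(f"series must start at midnight, starts at {ts[0]}")
    deltas = np.diff(ts.asi8)
    bad = np.nonzero(deltas != 60_000_000_000)[0]
    if bad.size:
        i = int(bad[0])
        if deltas[i] <= 0:
            raise SeriesValidationError(f"duplicate or out-of-order timestamp at row {i + 1}: {ts[i + 1]}")
        missing_minute = ts[i] + pd.Timedelta(minutes=1)
        raise SeriesValidationError(f"minute grid has a gap: first absent minute is {missing_minute}")
    steps = data["steps"].to_numpy(dtype=float)
    if np.nanmin(steps, initial=0.0) < 0:
        raise SeriesValidationError("negative step counts present")
    kcal = data["kcal"].to_numpy(dtype=float)
    if np.nanmin(kcal, initial=0.0) < 0:
        raise SeriesValidationError("negative energy values present")
    hr = data["heart_rate"].to_numpy(dtype=float)
    present = ~np.isnan(hr)
    if present.any() and ((hr[present] <= HR_LOW) | (hr[present] >= HR_HIGH)).any():
        raise SeriesValidationError(f"heart rate outside ({HR_LOW:g}, {HR_HIGH:g}) bpm present")
    # The non-wear rule (heart rate absent ⇒ steps/kcal missing) is enforced at
    # the I/O boundary by harmonize_missing; intermediate series completed one
    # channel at a time are permitted in memory.


def read_series(path: str | Path, mode: Literal["14-day", "free"] = "free") -> ParticipantSeries:
    """Load a participant series from the package CSV dialect.

    In ``14-day`` mode the file must contain exactly 20160 minute rows.
    Malformed timestamps, grid gaps, duplicate/out-of-order rows and negative
    counts all raise with the offending row or minute named.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "sex": str}, float_precision="round_trip")
    missing_cols = [c for c in CSV_HEADER if c not in df.columns]
    if missing_cols:
        raise SeriesValidationError(f"{path}: missing columns {missing_cols}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        # pinpoint the first bad row for the error message
        parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
        row = int(parsed.isna().idxmax()) if parsed.isna().any() else -1
        raise SeriesValidationError(f"{path}: malformed timestamp at row {row}: {exc}") from exc
    pid = df["participant_id"].iloc[0]
    if (df["participant_id"] != pid).any():
        raise SeriesValidationError(f"{path}: multiple participant_id values in one file")
    data = pd.DataFrame(
        {
            "timestamp": ts,
            "steps": pd.to_numeric(df["steps"], errors="raise"),
            "heart_rate": pd.to_numeric(df["heart_rate"], errors="raise"),
            "kcal": pd.to_numeric(df["kcal"], errors="raise"),
        }
    )
    series = ParticipantSeries(
        str(pid), float(df["age"].iloc[0]), str(df["sex"].iloc[0]), harmonize_missing(data)
    )
    if mode == "14-day" and len(series) != MINUTES_PER_PERIOD:
        raise SeriesValidationError(
            f"{path}: 14-day mode requires exactly {MINUTES_PER_PERIOD} rows, found {len(series)}"
        )
    return series


def write_series(series: ParticipantSeries, path: str | Path) -> None:
    """Write a series in the package CSV dialect (missing values = empty cells)."""
    out = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "age": series.age,
            "sex": series.sex,
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M"),
            "steps": series.data["steps"].to_numpy(),
            "heart_rate": series.data["heart_rate"].to_numpy(),
            "kcal": series.data["kcal"].to_numpy(),
        }
    )
    out.to_csv(path, index=False, na_rep="")
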