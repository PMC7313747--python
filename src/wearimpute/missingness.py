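"""Non-wear detection and simulated-missingness insertion.

Non-wear is defined by the absence of a heart-rate measure. Simulated
missingness follows the two study designs: independent random periods with
uniform start positions and integer lengths uniform on [1, 120] minutes
(40 periods in the first design), and ten incremental "windows" in which the
period count is drawn uniformly from 0–10, 10–20, …, 90–100. Overlapping
periods are applied as a union; periods running past the end of the series
are truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ParticipantSeries, harmonize_missing

DEFAULT_MAX_PERIOD_MINUTES = 120
STUDY1_N_PERIODS = 40
STUDY2_WINDOW_STEP = 10


@dataclass(frozen=True)
class MissingnessPlan:
    """A set of insertion periods: (start minute, length in minutes) pairs."""

    periods: tuple[tuple[int, int], ...]
    series_length: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for start, length in self.periods:
            if length < 1:
                raise ValueError(f"period length {length} < 1 minute")
            if not 0 <= start < self.series_length:
                raise ValueError(f"period start {start} outside [0, {self.series_length})")

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def coverage(self) -> np.ndarray:
        """Boolean mask of minutes covered by the union of all periods."""
        mask = np.zeros(self.series_length, dtype=bool)
        for start, length in self.periods:
            mask[start : min(start + length, self.series_length)] = True
        return mask


def detect_nonwear(series: ParticipantSeries) -> np.ndarray:
    """Per-minute wear mask: True where the device was worn (HR present)."""
    return series.worn


def draw_plan(
    n_periods: int,
    series_length: int,
    max_len: int = DEFAULT_MAX_PERIOD_MINUTES,
    seed: int | np.random.SeedSequence | None = None,
) -> MissingnessPlan:
    """Draw independent insertion periods.

    Starts are uniform over the whole grid and integer lengths uniform on
    [1, max_len]; periods may overlap (union semantics downstream) and are
    truncated at the series end when applied.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1 minute")
    if n_periods < 0:
        raise ValueError("n_periods must be >= 0")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, series_length, size=n_periods)
    lengths = rng.integers(1, max_len + 1, size=n_periods)
    return MissingnessPlan(
        periods=tuple((int(s), int(l)) for s, l in zip(starts, lengths)),
        series_length=series_length,
        seed=seed if isinstance(seed, int) else None,
    )


def apply_plan(
    series: ParticipantSeries, plan: MissingnessPlan
) -> tuple[ParticipantSeries, np.ndarray]:
    """Blank all channels on the union of the plan's periods.

    Returns the masked series and an ``inserted`` mask marking exactly the
    minutes newly blanked (i.e. previously worn). The input series is left
    untouched.
    """
    if plan.series_length != len(series):
        raise ValueError("plan drawn for a different series length")
    cover = plan.coverage()
    inserted = cover & series.worn
    data = series.data.copy()
    data.loc[cover, ["steps", "heart_rate", "kcal"]] = np.nan
    return series.replace_data(harmonize_missing(data)), inserted


def study2_period_count(
    window_index: int, seed: int | np.random.SeedSequence | None = None
) -> int:
    """Number of insertion periods for one incremental-missingness window.

    Window w ∈ 1..10 draws uniformly from {10(w−1), …, 10w} inclusive.
    """
    if not 1 <= window_index <= 10:
        raise ValueError("window_index must be in 1..10")
    rng = np.random.default_rng(seed)
    lo = STUDY2_WINDOW_STEP * (window_index - 1)
    hi = STUDY2_WINDOW_STEP * window_index
    return int(rng.integers(lo, hi + 1))
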