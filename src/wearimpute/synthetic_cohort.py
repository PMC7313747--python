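"""Synthetic 14-day minute-level activity cohorts with circadian structure.

The generator emulates the shape of free-living wrist-monitor data: a nightly
sleep window with near-zero movement and low, stable heart rate; a sedentary
waking baseline of occasional steps; discrete activity bouts arriving as a
Poisson process with uniform lengths and cadences; heart rate coupled
linearly to cadence within the participant's heart-rate reserve plus AR(1)
noise; and energy expenditure as a linear function of cadence above a basal
rate. Each profile is calibrated so that expected daily steps match a target,
and cohort-level defaults are tuned to a middle-aged European weight-loss-
maintenance population (~10,500 steps/day, TDEE ~2,600 kcal/day).

Everything is driven by explicit seeds: the same seed reproduces a cohort
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import time

import numpy as np
import pandas as pd

from . import hrr_intensity
from .datamodel import MINUTES_PER_DAY, MINUTES_PER_PERIOD, ParticipantSeries, build_series

HR_CADENCE_FRACTION = 0.9  # peak-cadence HR reaches 90% of heart-rate reserve
AR1_COEFFICIENT = 0.8  # waking HR noise persistence (minutes)
ENERGY_CADENCE_GAIN = 4.0  # kcal multiplier at peak cadence relative to basal


@dataclass(frozen=True)
class ParticipantProfile:
    """Behavioural and physiological parameters of one synthetic participant."""

    age: float = 47.0
    sex: str = "female"
    sleep_window: tuple[time, time] = (time(23, 0), time(7, 0))
    sleep_hr: float = 52.0
    target_daily_steps: float = 10_500.0
    bout_rate: float = 3.3  # expected activity bouts per day
    bout_length_range: tuple[int, int] = (5, 40)  # minutes
    bout_cadence_range: tuple[float, float] = (25.0, 115.0)  # steps/min
    sedentary_step_rate: float = 4.0  # mean steps/min outside bouts, awake
    hr_noise_sd: float = 3.0  # bpm
    basal_kcal_per_min: float = 1.45

    def __post_init__(self) -> None:
        if self.bout_length_range[0] > self.bout_length_range[1]:
            raise ValueError("bout_length_range low > high")
        if self.bout_cadence_range[0] > self.bout_cadence_range[1]:
            raise ValueError("bout_cadence_range low > high")
        for name in ("bout_rate", "sedentary_step_rate", "hr_noise_sd", "basal_kcal_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        hr_rest = hrr_intensity.resting_heart_rate(self.sleep_hr)
        hr_max = hrr_intensity.max_heart_rate(self.age)
        if not self.sleep_hr < hr_rest < hr_max:
            raise ValueError("require sleep HR < resting HR < max HR")

    @property
    def sleep_minutes_per_day(self) -> int:
        start, end = self.sleep_window
        s, e = start.hour * 60 + start.minute, end.hour * 60 + end.minute
        return (e - s) % MINUTES_PER_DAY

    @property
    def waking_minutes_per_day(self) -> int:
        return MINUTES_PER_DAY - self.sleep_minutes_per_day


def calibrated_profile(**overrides) -> ParticipantProfile:
    """A profile whose bout rate is set so expected daily steps hit the target.

    Expected steps/day = sedentary_rate × (waking − C) + mean_cadence × C,
    where C is the expected waking coverage of the bout process. Because
    bouts overlap (later bouts overwrite) the coverage of a Poisson bout
    process is waking·(1 − exp(−rate·E[len]/waking)); the rate is solved by
    inverting that relation for the coverage the target requires.
    """
    base = ParticipantProfile(**{k: v for k, v in overrides.items() if k != "bout_rate"})
    waking = base.waking_minutes_per_day
    mean_len = (base.bout_length_range[0] + base.bout_length_range[1]) / 2.0
    mean_cad = (base.bout_cadence_range[0] + base.bout_cadence_range[1]) / 2.0
    surplus = base.target_daily_steps - base.sedentary_step_rate * waking
    if surplus <= 0 or mean_cad <= base.sedentary_step_rate or mean_len == 0:
        return replace(base, bout_rate=0.0)
    coverage = min(surplus / (mean_cad - base.sedentary_step_rate), 0.99 * waking)
    rate = -waking * np.log(1.0 - coverage / waking) / mean_len
    return replace(base, bout_rate=float(rate))


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for a cohort of participant profiles.

    Ages are Normal(47.5, 9.6) clipped to [22, 75]; daily step targets
    Normal(10570, 3209) clipped to [3500, 19500]; TDEE targets Normal(2626,
    505) clipped to [1800, 4400] and converted to a basal kcal/min rate;
    sleeping HR Normal(52, 5) clipped to [42, 68]; sex female with
    probability 93/109. These families centre on a middle-aged, mostly
    female weight-loss-maintenance cohort.
    """

    n_participants: int = 10
    seed: int | None = None
    age_mean: float = 47.46
    age_sd: float = 9.62
    steps_mean: float = 10_570.0
    steps_sd: float = 3_209.0
    tdee_mean: float = 2_626.0
    tdee_sd: float = 505.0
    sleep_hr_mean: float = 52.0
    sleep_hr_sd: float = 5.0
    female_fraction: float = 93 / 109

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")


def sample_profile(config: CohortConfig, rng: np.random.Generator) -> ParticipantProfile:
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 22, 75))
    target_steps = float(np.clip(rng.normal(config.steps_mean, config.steps_sd), 3_500, 19_500))
    target_tdee = float(np.clip(rng.normal(config.tdee_mean, config.tdee_sd), 1_800, 4_400))
    sleep_hr = float(np.clip(rng.normal(config.sleep_hr_mean, config.sleep_hr_sd), 42, 68))
    sex = "female" if rng.random() < config.female_fraction else "male"
    sedentary_rate = float(rng.uniform(2.0, 6.0))
    peak_cadence = 115.0
    # invert TDEE = basal * (1440 + gain * steps / peak)
    basal = target_tdee / (MINUTES_PER_DAY + ENERGY_CADENCE_GAIN * target_steps / peak_cadence)
    return calibrated_profile(
        age=age,
        sex=sex,
        sleep_hr=sleep_hr,
        target_daily_steps=target_steps,
        sedentary_step_rate=sedentary_rate,
        hr_noise_sd=float(rng.uniform(2.0, 4.0)),
        basal_kcal_per_min=basal,
        bout_cadence_range=(25.0, peak_cadence),
    )


def _sleep_mask(profile: ParticipantProfile, minutes_of_day: np.ndarray) -> np.ndarray:
    start, end = profile.sleep_window
    s = start.hour * 60 + start.minute
    e = end.hour * 60 + end.minute
    if s <= e:
        return (minutes_of_day >= s) & (minutes_of_day < e)
    return (minutes_of_day >= s) | (minutes_of_day < e)


def generate_participant(
    profile: ParticipantProfile,
    seed: int | np.random.SeedSequence,
    participant_id: str = "P000",
    n_days: int = 14,
) -> ParticipantSeries:
    """Simulate one participant's complete minute-level series.

    The series spans ``n_days`` (default 14 → 20160 minutes) with no missing
    minutes. Sleep minutes carry zero steps and heart rate around the sleeping
    level; waking minutes carry Poisson step counts at either the sedentary
    baseline cadence or an active bout cadence, with heart rate coupled to
    cadence inside the participant's heart-rate reserve.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    n = n_days * MINUTES_PER_DAY
    grid = np.arange(n)
    minutes_of_day = grid % MINUTES_PER_DAY
    asleep = _sleep_mask(profile, minutes_of_day)

    # expected cadence per minute: sedentary baseline, overwritten by bouts
    cadence = np.full(n, float(profile.sedentary_step_rate))
    lo_len, hi_len = profile.bout_length_range
    lo_cad, hi_cad = profile.bout_cadence_range
    waking_idx_by_day = [
        np.nonzero(~asleep[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY])[0] + d * MINUTES_PER_DAY
        for d in range(n_days)
    ]
    for d in range(n_days):
        for _ in range(rng.poisson(profile.bout_rate)):
            waking = waking_idx_by_day[d]
            if waking.size == 0:
                continue
            start = int(rng.choice(waking))
            length = int(rng.integers(lo_len, hi_len + 1))
            cad = float(rng.uniform(lo_cad, hi_cad))
            stop = min(start + length, n)
            span = slice(start, stop)
            keep = ~asleep[span]  # bouts never run into the sleep window
            cadence[span][keep] = cad
    cadence[asleep] = 0.0

    steps = rng.poisson(cadence).astype(float)
    steps[asleep] = 0.0

    hr_max = hrr_intensity.max_heart_rate(profile.age)
    hr_rest = hrr_intensity.resting_heart_rate(profile.sleep_hr)
    peak_cadence = hi_cad if hi_cad > 0 else 1.0
    reserve = hr_max - hr_rest
    hr = np.empty(n)
    hr[asleep] = rng.normal(profile.sleep_hr, profile.hr_noise_sd, size=int(asleep.sum()))
    # AR(1) noise on waking minutes, stationary at hr_noise_sd
    innov_sd = profile.hr_noise_sd * np.sqrt(1 - AR1_COEFFICIENT**2)
    noise = np.zeros(n)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, profile.hr_noise_sd)
    noise[0] = eps[0]
    for i in range(1, n):
        noise[i] = AR1_COEFFICIENT * noise[i - 1] + eps[i]
    awake = ~asleep
    hr[awake] = (
        hr_rest
        + (cadence[awake] / peak_cadence) * reserve * HR_CADENCE_FRACTION
        + noise[awake]
    )
    hr = np.clip(hr, 25.0 + 1e-6, 250.0 - 1e-6)

    kcal = profile.basal_kcal_per_min * (1.0 + ENERGY_CADENCE_GAIN * steps / peak_cadence)

    return build_series(participant_id, profile.age, profile.sex, steps, hr, kcal)


def generate_cohort(config: CohortConfig) -> list[ParticipantSeries]:
    """Simulate ``n_participants`` independent 14-day series from one seed."""
    root = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    participant_seeds = root.spawn(config.n_participants + 1)[1:]
    cohort = []
    for i, ss in enumerate(participant_seeds):
        profile = sample_profile(config, profile_rng)
        cohort.append(generate_participant(profile, ss, participant_id=f"P{i:03d}"))
    return cohort
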