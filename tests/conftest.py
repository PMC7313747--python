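import numpy as np
import pytest

import wearimpute as wi


def series_from_channels(steps, heart_rate, kcal, pid="T00", age=40.0, sex="female"):
    """Small helper: build a validated series from raw channel arrays."""
    return wi.build_series(pid, age, sex, steps, heart_rate, kcal)


def constant_day(steps_per_min=10.0, hr=100.0, kcal=1.5, n_days=1):
    """A fully worn series with identical values every minute."""
    n = n_days * 1440
    return series_from_channels(
        np.full(n, float(steps_per_min)), np.full(n, float(hr)), np.full(n, float(kcal))
    )


@pytest.fixture(scope="session")
def participant():
    """One complete synthetic 14-day participant."""
    return wi.generate_participant(wi.calibrated_profile(), seed=42)


@pytest.fixture(scope="session")
def masked_participant(participant):
    """The same participant with 40 random missing periods inserted."""
    plan = wi.draw_plan(40, len(participant), seed=7)
    masked, inserted = wi.apply_plan(participant, plan)
    return masked, inserted


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic participants (kept small; the acceptance suite uses 30)."""
    return wi.generate_cohort(wi.CohortConfig(n_participants=4, seed=202))
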