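import numpy as np
import pytest

import wearimpute as wi
from wearimpute import imputers
from wearimpute.missingness import MissingnessPlan

from conftest import constant_day, series_from_channels


def _gappy_series(seed=0, n_days=2, n_gaps=6):
    rng = np.random.default_rng(seed)
    n = n_days * 1440
    steps = rng.poisson(6, n).astype(float)
    hr = 70 + 8 * rng.standard_normal(n)
    kcal = 1.2 + 0.05 * steps
    s = series_from_channels(steps, hr, kcal)
    plan = wi.draw_plan(n_gaps, n, seed=seed + 1)
    masked, _ = wi.apply_plan(s, plan)
    return s, masked


@pytest.mark.parametrize(
    "method",
    ["individual_mean", "individual_mi", "random_forest", "kalman"],
)
def test_observed_minutes_are_never_altered(method):
    _, masked = _gappy_series()
    result = imputers.run_method(method, masked, seed=5)
    worn = masked.worn
    for ch in ("steps", "heart_rate", "kcal"):
        np.testing.assert_array_equal(
            result.completed.channel(ch)[worn], masked.channel(ch)[worn]
        )
        assert not np.isnan(result.completed.channel(ch)).any()


@pytest.mark.parametrize(
    "method", ["individual_mean", "individual_mi", "random_forest", "kalman"]
)
def test_complete_series_passes_through_unchanged(method):
    s = constant_day(steps_per_min=3.0, n_days=2)
    result = imputers.run_method(method, s, seed=1)
    for ds in result.datasets:
        assert ds.equals(s)


def test_mean_imputation_fills_with_the_scope_mean():
    steps = np.full(1440, 7.0)
    hr = np.full(1440, 80.0)
    kcal = np.full(1440, 1.5)
    s = series_from_channels(steps, hr, kcal)
    masked, _ = wi.apply_plan(s, MissingnessPlan(((100, 30),), 1440))
    filled = wi.impute_mean(masked).completed
    np.testing.assert_allclose(filled.channel("steps")[100:130], 7.0)
    np.testing.assert_allclose(filled.channel("heart_rate")[100:130], 80.0)


def test_overall_and_individual_means_differ_when_cohorts_differ():
    quiet = constant_day(steps_per_min=2.0)
    busy = constant_day(steps_per_min=20.0)
    masked, _ = wi.apply_plan(quiet, MissingnessPlan(((0, 10),), 1440))
    ind = wi.impute_mean(masked, "individual").completed.channel("steps")[0]
    ovr = wi.impute_mean(masked, "overall", cohort=[masked, busy]).completed.channel("steps")[0]
    assert ind == pytest.approx(2.0)
    assert ovr > ind


def test_mean_imputation_rejects_all_missing_channel():
    s = constant_day()
    masked, _ = wi.apply_plan(s, MissingnessPlan(((0, 1440),), 1440))
    with pytest.raises(ValueError):
        wi.impute_mean(masked)


def test_pmm_copies_values_from_the_observed_donor_set():
    _, masked = _gappy_series(seed=3)
    result = wi.impute_multiple_pmm(masked, "individual", seed=9)
    assert result.m_datasets == 7 and len(result.datasets) == 7
    for ch in ("steps", "heart_rate", "kcal"):
        observed = set(masked.channel(ch)[masked.worn])
        for ds in result.datasets:
            imputed = ds.channel(ch)[~masked.worn]
            assert set(imputed) <= observed


def test_pmm_overall_scope_defaults_to_five_imputations():
    full, masked = _gappy_series(seed=4)
    result = wi.impute_multiple_pmm(masked, "overall", seed=2, cohort=[masked, full])
    assert result.m_datasets == 5


def test_kalman_fills_constant_channel_exactly():
    s = constant_day(steps_per_min=4.0, hr=75.0, n_days=1)
    masked, _ = wi.apply_plan(s, MissingnessPlan(((200, 60), (900, 30)), 1440))
    filled = wi.impute_kalman(masked, seed=0).completed
    np.testing.assert_allclose(filled.channel("steps"), 4.0, atol=1e-6)
    np.testing.assert_allclose(filled.channel("heart_rate"), 75.0, atol=1e-6)


def test_kalman_ramp_fill_matches_gaussian_conditioning_oracle():
    """The smoother's fill of an interior gap must agree with exact Gaussian
    conditioning under the same fitted local-level variances."""
    n = 1440
    line = 60.0 + 0.02 * np.arange(n)
    hr = line.copy()
    hr[700:710] = np.nan
    steps = np.zeros(n)
    steps[700:710] = np.nan
    s = series_from_channels(steps, hr, np.ones(n))
    result = imputers.impute_kalman(s, seed=0, channels=("heart_rate",))
    fill = result.completed.channel("heart_rate")[700:710]
    assert np.abs(fill - line[700:710]).max() < 1e-3

    q = result.params["heart_rate"]["level_var"]
    r = result.params["heart_rate"]["obs_var"]
    idx = np.arange(n)
    cov = 1e9 + q * np.minimum.outer(idx + 1.0, idx + 1.0) + r * np.eye(n)
    obs = ~np.isnan(hr)
    oracle = cov[np.ix_(~obs, obs)] @ np.linalg.solve(cov[np.ix_(obs, obs)], line[obs])
    np.testing.assert_allclose(fill, oracle, atol=1e-3)


def test_kalman_requires_minimum_observations():
    hr = np.full(1440, np.nan)
    hr[:5] = 80.0
    s = series_from_channels(np.zeros(1440), hr, np.ones(1440))
    with pytest.raises(ValueError, match="observed"):
        wi.impute_kalman(s, seed=0, channels=("heart_rate",))


def test_random_forest_stays_within_observed_range_and_is_seeded():
    _, masked = _gappy_series(seed=6)
    a = wi.impute_random_forest(masked, seed=21)
    b = wi.impute_random_forest(masked, seed=21)
    for ch in ("steps", "heart_rate", "kcal"):
        observed = masked.channel(ch)[masked.worn]
        imputed = a.completed.channel(ch)[~masked.worn]
        assert imputed.min() >= observed.min() - 1e-9
        assert imputed.max() <= observed.max() + 1e-9
        np.testing.assert_array_equal(a.completed.channel(ch), b.completed.channel(ch))


def test_imputed_values_respect_physiological_bounds():
    _, masked = _gappy_series(seed=8)
    for method in ("individual_mean", "individual_mi", "kalman"):
        completed = imputers.run_method(method, masked, seed=3).completed
        assert completed.channel("steps").min() >= 0
        hr = completed.channel("heart_rate")
        assert hr.min() > 25 and hr.max() < 250
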