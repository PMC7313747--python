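import numpy as np
import pytest
from scipy import stats

import wearimpute as wi
from wearimpute import evaluation

from conftest import series_from_channels


# -- RMSE -------------------------------------------------------------------

@pytest.mark.parametrize(
    "pred, true, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 0], [3, 4], np.sqrt(12.5)),
        ([1], [4], 3.0),
    ],
)
def test_rmse_worked_examples(pred, true, expected):
    assert wi.rmse(np.array(pred), np.array(true)) == pytest.approx(expected)


def test_rmse_matches_direct_recomputation():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.normal(size=(2, 17))
        direct = float(np.sqrt(np.sum((a - b) ** 2) / len(a)))
        assert wi.rmse(a, b) == pytest.approx(direct, abs=1e-12)


# -- equivalence (TOST) -----------------------------------------------------

def test_zero_differences_are_equivalent_with_zero_pvalues():
    x = np.array([10.0, 12.0, 9.0])
    out = wi.equivalence_test(x, x)
    assert out.equivalent and out.p_lower == 0.0 and out.p_upper == 0.0


def test_large_positive_bias_is_not_equivalent():
    true = np.full(20, 100.0) + np.random.default_rng(1).normal(0, 0.01, 20)
    imputed = true + 50.0
    out = wi.equivalence_test(imputed, true)
    assert not out.equivalent
    assert out.p_upper > 0.99


def test_equivalence_verdict_matches_90pct_ci_containment():
    """On 1000 random paired fixtures, TOST equivalence must coincide exactly
    with the 90% confidence interval lying inside ±10% of the true mean."""
    rng = np.random.default_rng(42)
    mismatches = 0
    for _ in range(1000):
        n = int(rng.integers(3, 40))
        true = rng.normal(100, 20, n)
        imputed = true + rng.normal(rng.uniform(-15, 15), rng.uniform(0.5, 20), n)
        out = wi.equivalence_test(imputed, true)
        d = imputed - true
        half = stats.t.ppf(0.95, n - 1) * d.std(ddof=1) / np.sqrt(n)
        ci_inside = (d.mean() - half > -out.bound) and (d.mean() + half < out.bound)
        mismatches += ci_inside != out.equivalent
    assert mismatches == 0


def test_equivalence_requires_pairs():
    with pytest.raises(ValueError):
        wi.equivalence_test(np.array([1.0]), np.array([1.0]))


# -- ICC --------------------------------------------------------------------

def _icc_oracle(table):
    """Brute-force two-way ANOVA mean squares from explicit sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    msr = k * sum((table[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((table[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (table[i, j] - table[i].mean() - table[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def test_icc_perfect_agreement():
    col = np.array([1.0, 2.0, 3.0, 4.0])
    out = wi.icc_agreement(np.column_stack([col, col]))
    assert out.icc == pytest.approx(1.0)


def test_icc_of_independent_noise_is_near_zero():
    rng = np.random.default_rng(5)
    table = rng.normal(size=(1000, 2))
    assert abs(wi.icc_agreement(table).icc) < 0.1


def test_icc_matches_anova_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(4, 12))
        k = int(rng.integers(2, 5))
        table = rng.integers(0, 20, size=(n, k)).astype(float)
        if np.ptp(table) == 0:
            continue
        assert wi.icc_agreement(table).icc == pytest.approx(_icc_oracle(table), abs=1e-10)


def test_icc_cross_checked_against_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(3)
    table = rng.normal(10, 2, size=(8, 3))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": table.ravel(),
        }
    )
    ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert wi.icc_agreement(table).icc == pytest.approx(icc2, abs=1e-8)


def test_icc_rejects_degenerate_tables():
    with pytest.raises(ValueError):
        wi.icc_agreement(np.ones((4, 2)))


# -- wear-time requirement curves ------------------------------------------

def test_wear_requirement_curves(small_cohort):
    cohort = small_cohort[:2]
    hour = wi.wear_requirement_curve(cohort, "hour", seed=1)
    day = wi.wear_requirement_curve(cohort, "day", seed=1)
    period = wi.wear_requirement_curve(cohort, "period", seed=1)
    for curve in (hour, day, period):
        assert curve.loc[curve.units_deleted == 0, "icc"].iloc[0] == pytest.approx(1.0)
    # broadly decreasing with deletion: compare first vs last third
    tail = hour[hour.units_deleted > 36]["icc"].mean()
    head = hour[(hour.units_deleted > 0) & (hour.units_deleted <= 18)]["icc"].mean()
    assert tail <= head
    assert evaluation.minimum_retained(hour) is not None


def test_scaling_is_exact_for_constant_rate_hours():
    """Deleting 55 of 60 minutes from internally constant hours keeps ICC at 1."""
    rng = np.random.default_rng(2)
    per_hour = rng.uniform(1, 10, size=24)  # constant within each hour
    steps = np.repeat(per_hour, 60)
    s = series_from_channels(steps, np.full(1440, 80.0), np.ones(1440))
    curve = wi.wear_requirement_curve([s, s], "hour", seed=3)
    assert curve.loc[curve.units_deleted == 55, "icc"].iloc[0] == pytest.approx(1.0)


# -- autocorrelation --------------------------------------------------------

def test_acf_of_white_noise_is_negligible():
    rng = np.random.default_rng(8)
    hr = 80 + rng.standard_normal(20160)
    s = series_from_channels(rng.poisson(5, 20160).astype(float), hr, np.ones(20160))
    prof = wi.acf_profile(s, "heart_rate", max_lag=2000)
    assert prof[0] == pytest.approx(1.0)
    assert np.abs(prof[1:]).max() < 0.05


def test_acf_of_daily_periodic_signal_peaks_at_1440():
    t = np.arange(20160)
    hr = 80 + 10 * np.sin(2 * np.pi * t / 1440)
    s = series_from_channels(np.zeros(20160), hr, np.ones(20160))
    prof = wi.acf_profile(s, "heart_rate", max_lag=1500)
    # the standard (biased) ACF estimator shrinks by (n − k)/n at lag k
    assert prof[1440] == pytest.approx(1.0 - 1440 / 20160, abs=0.02)
    assert prof[1440] == prof[1000:1501].max()


def test_generated_hr_is_more_autocorrelated_than_steps(participant):
    hr_acf = wi.acf_profile(participant, "heart_rate", max_lag=15)[15]
    steps_acf = wi.acf_profile(participant, "steps", max_lag=15)[15]
    assert hr_acf > steps_acf


# -- simulation studies -----------------------------------------------------

def test_study1_table_shape_and_removal_bias(small_cohort):
    table = evaluation.run_study1(
        small_cohort,
        methods=("removal", "nohow", "individual_mean"),
        seed=6,
        metrics=("steps", "tdee"),
    )
    assert len(table) == 3 * 2 * 3  # methods × metrics × levels
    removal = table[table.method == "removal"]
    assert (removal.mean_diff <= 0).all()  # treating missing as zero undercounts


def test_study1_without_missingness_has_zero_rmse(small_cohort):
    table = evaluation.run_study1(
        small_cohort[:2],
        methods=("removal", "nohow", "individual_mean"),
        n_periods=0,
        seed=2,
        metrics=("steps",),
    )
    assert np.allclose(table.rmse, 0.0)


def test_study2_is_deterministic_and_window_counts():
    cohort = wi.generate_cohort(wi.CohortConfig(n_participants=1, seed=12))
    kwargs = dict(
        methods=("nohow",), windows=(1, 10), sims_per_window=2, seed=4, metrics=("steps",)
    )
    a = evaluation.run_study2(cohort, **kwargs)
    b = evaluation.run_study2(cohort, **kwargs)
    assert a.equals(b)
    assert len(a) == 1 * 2 * 2 * 1 * 1  # participants × windows × sims × methods × metrics
    wr = evaluation.study2_window_rmse(a)
    assert set(wr.window) <= {1, 10}
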