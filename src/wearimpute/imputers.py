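"""Minute-level imputation strategies for non-wear gaps.

Four families of comparator methods, all filling the three channels (steps,
heart rate, kcal) at non-worn minutes while leaving observed minutes
untouched:

* mean imputation — the plain mean of the observed minutes, computed either
  over the whole cohort ("overall") or per participant ("individual");
* multiple imputation by bootstrapped predictive mean matching (PMM) — for
  each of m imputations a bootstrap resample of the observed minutes fits a
  linear predictor (overall scope: age, sex, day of week; individual scope:
  day of week and hour of day), and each missing minute copies the observed
  value of one of the 5 donors whose predictions are nearest its own;
* iterative random-forest imputation — channels are initialised at their
  means and repeatedly re-predicted from weekday, hour and the other
  channels' current values with a 100-tree forest, until the change between
  successive imputations stops decreasing (at most 5 iterations);
* Kalman smoothing under a local-level structural model — per channel a
  Gaussian random-walk level plus observation noise is fit by maximum
  likelihood on the observed sequence, and missing minutes take the smoothed
  state mean.

Imputed steps and kcal are clipped below at 0 and imputed heart rate to the
physiological band (25, 250) bpm. Category metrics are never imputed
directly: heart rate is imputed and then classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CHANNELS, ParticipantSeries

PMM_DONORS = 5
DEFAULT_M_OVERALL = 5
DEFAULT_M_INDIVIDUAL = 7
RF_TREES = 100
RF_MAX_ITER = 5
KALMAN_MIN_OBSERVED = 10

_HR_EPS = 1e-6


@dataclass
class ImputationResult:
    """A completed series (plus per-imputation completions for MI)."""

    completed: ParticipantSeries
    method: str
    m_datasets: int = 1
    datasets: list[ParticipantSeries] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.datasets:
            self.datasets = [self.completed]


def _clip_channel(channel: str, values: np.ndarray) -> np.ndarray:
    if channel == "heart_rate":
        return np.clip(values, 25.0 + _HR_EPS, 250.0 - _HR_EPS)
    return np.maximum(values, 0.0)


def _complete(target: ParticipantSeries, filled: dict[str, np.ndarray]) -> ParticipantSeries:
    """New series with missing entries replaced; observed entries untouched."""
    data = target.data.copy()
    for ch, values in filled.items():
        col = data[ch].to_numpy(dtype=float).copy()
        miss = np.isnan(col)
        col[miss] = _clip_channel(ch, values[miss])
        data[ch] = col
    return target.replace_data(data)


def impute_mean(
    target: ParticipantSeries,
    scope: str = "individual",
    cohort: list[ParticipantSeries] | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> ImputationResult:
    """Fill every missing minute with the observed channel mean over the scope."""
    if scope not in ("individual", "overall"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "overall" and cohort is None:
        raise ValueError("overall scope requires the cohort")
    sources = cohort if scope == "overall" else [target]
    filled = {}
    for ch in channels:
        pooled = np.concatenate([s.channel(ch) for s in sources])
        if np.all(np.isnan(pooled)):
            raise ValueError(f"channel {ch!r} has no observed minutes in scope")
        filled[ch] = np.full(len(target), float(np.nanmean(pooled)))
    return ImputationResult(_complete(target, filled), f"{scope}_mean")


def _design_individual(ts: pd.DatetimeIndex) -> np.ndarray:
    """Intercept + day-of-week and hour-of-day indicator columns."""
    dow = np.asarray(ts.weekday)
    hour = np.asarray(ts.hour)
    cols = [np.ones(len(ts))]
    cols += [(dow == d).astype(float) for d in range(1, 7)]
    cols += [(hour == h).astype(float) for h in range(1, 24)]
    return np.column_stack(cols)


def _design_overall(ts: pd.DatetimeIndex, age: float, sex: str) -> np.ndarray:
    """Intercept + age, sex and day-of-week columns."""
    dow = np.asarray(ts.weekday)
    cols = [np.ones(len(ts)), np.full(len(ts), age), np.full(len(ts), 1.0 if sex == "female" else 0.0)]
    cols += [(dow == d).astype(float) for d in range(1, 7)]
    return np.column_stack(cols)


def _pmm_fill(
    donor_values: np.ndarray,
    donor_pred: np.ndarray,
    miss_pred: np.ndarray,
    rng: np.random.Generator,
    k: int = PMM_DONORS,
) -> np.ndarray:
    """Copy, for each missing prediction, one of the k nearest donors' values."""
    order = np.argsort(donor_pred, kind="stable")
    sorted_pred = donor_pred[order]
    sorted_val = donor_values[order]
    pos = np.searchsorted(sorted_pred, miss_pred)
    # candidate window of 2k neighbours around the insertion point
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, len(sorted_pred) - 1)
    dist = np.abs(sorted_pred[cand] - miss_pred[:, None])
    nearest = np.argpartition(dist, kth=min(k, dist.shape[1]) - 1, axis=1)[:, :k]
    choice = rng.integers(0, nearest.shape[1], size=len(miss_pred))
    picked = cand[np.arange(len(miss_pred)), nearest[np.arange(len(miss_pred)), choice]]
    return sorted_val[picked]


def impute_multiple_pmm(
    target: ParticipantSeries,
    scope: str = "individual",
    m: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    cohort: list[ParticipantSeries] | None = None,
    k_donors: int = PMM_DONORS,
    channels: tuple[str, ...] = CHANNELS,
) -> ImputationResult:
    """Multiple imputation with bootstrapping and predictive mean matching.

    Defaults to m = 5 imputations in the overall scope and m = 7 in the
    individual scope. The point completion returned as ``completed`` averages
    the m completed datasets element-wise; summary statistics should be
    computed per dataset and averaged.
    """
    if scope not in ("individual", "overall"):
        raise ValueError(f"unknown scope {scope!r}")
    if m is None:
        m = DEFAULT_M_INDIVIDUAL if scope == "individual" else DEFAULT_M_OVERALL
    if m < 1:
        raise ValueError("m must be >= 1")
    if scope == "overall" and cohort is None:
        raise ValueError("overall scope requires the cohort")
    rng = np.random.default_rng(seed)

    if scope == "individual":
        sources = [target]
        designs = {id(target): _design_individual(target.timestamps)}
    else:
        sources = list(cohort)
        designs = {id(s): _design_overall(s.timestamps, s.age, s.sex) for s in sources}
    X_target = (
        designs[id(target)]
        if id(target) in designs
        else _design_overall(target.timestamps, target.age, target.sex)
    )

    per_channel: dict[str, np.ndarray] = {}
    fills: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    for ch in channels:
        y_parts, X_parts = [], []
        for s in sources:
            y = s.channel(ch)
            obs = ~np.isnan(y)
            y_parts.append(y[obs])
            X_parts.append(designs[id(s)][obs])
        y_obs = np.concatenate(y_parts)
        X_obs = np.vstack(X_parts)
        miss = np.isnan(target.channel(ch))
        if X_obs.shape[0] <= X_obs.shape[1]:
            raise ValueError(f"channel {ch!r}: fewer observed minutes than predictors")
        per_channel[ch] = miss
        X_miss = X_target[miss]
        for _ in range(m):
            boot = rng.integers(0, len(y_obs), size=len(y_obs))
            beta, *_ = np.linalg.lstsq(X_obs[boot], y_obs[boot], rcond=None)
            donor_pred = X_obs @ beta
            miss_pred = X_miss @ beta
            if miss.any():
                fills[ch].append(_pmm_fill(y_obs, donor_pred, miss_pred, rng, k_donors))
            else:
                fills[ch].append(np.empty(0))

    datasets = []
    for j in range(m):
        filled = {}
        for ch in channels:
            values = np.zeros(len(target))
            values[per_channel[ch]] = fills[ch][j]
            filled[ch] = values
        datasets.append(_complete(target, filled))
    mean_fill = {}
    for ch in channels:
        stack = np.stack([d.channel(ch) for d in datasets])
        mean_fill[ch] = stack.mean(axis=0)
    completed = _complete(target, mean_fill)
    return ImputationResult(completed, f"{scope}_mi", m_datasets=m, datasets=datasets)


def impute_random_forest(
    target: ParticipantSeries,
    n_trees: int = RF_TREES,
    max_iter: int = RF_MAX_ITER,
    seed: int | np.random.SeedSequence | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> ImputationResult:
    """Iterative random-forest imputation from weekday, hour and co-channels.

    Channels are initialised at their observed means and revisited in order
    of increasing missingness; each pass refits a forest (``n_trees`` trees,
    √p variables per split, minimum leaf size 5) on the observed minutes and
    re-predicts the missing ones. Iteration stops when the aggregate change
    between successive imputations stops decreasing, or after ``max_iter``
    passes, returning the last improving imputation.
    """
    from sklearn.ensemble import RandomForestRegressor

    rng = np.random.default_rng(seed)
    ts = target.timestamps
    X_base = np.column_stack([np.asarray(ts.weekday, dtype=float), np.asarray(ts.hour, dtype=float)])
    current: dict[str, np.ndarray] = {}
    miss_masks: dict[str, np.ndarray] = {}
    for ch in channels:
        y = target.channel(ch)
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError(f"channel {ch!r} has no observed minutes")
        miss_masks[ch] = ~obs
        y0 = y.copy()
        y0[~obs] = np.nanmean(y)
        current[ch] = y0
    order = sorted(channels, key=lambda ch: miss_masks[ch].sum())

    prev_diff = np.inf
    best = {ch: current[ch].copy() for ch in channels}
    for _ in range(max_iter):
        old = {ch: current[ch].copy() for ch in channels}
        for ch in order:
            miss = miss_masks[ch]
            if not miss.any():
                continue
            others = [current[o] for o in channels if o != ch]
            X = np.column_stack([X_base] + others) if others else X_base
            obs = ~miss
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                min_samples_leaf=5,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(X[obs], current[ch][obs])
            current[ch][miss] = forest.predict(X[miss])
        num = sum(float(np.sum((current[ch] - old[ch]) ** 2)) for ch in channels)
        den = sum(float(np.sum(current[ch] ** 2)) for ch in channels)
        diff = num / den if den > 0 else 0.0
        if diff >= prev_diff:
            break  # change stopped decreasing: keep the previous imputation
        best = {ch: current[ch].copy() for ch in channels}
        prev_diff = diff
        if diff == 0.0:
            break
    return ImputationResult(_complete(target, best), "random_forest")


def impute_kalman(
    target: ParticipantSeries,
    seed: int | np.random.SeedSequence | None = None,
    seasonal_period: int | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> ImputationResult:
    """Kalman smoothing under a maximum-likelihood local-level model.

    Per channel, a Gaussian structural model with a random-walk level
    (variance q) and observation noise (variance r) is fit on the observed
    sequence; the Kalman smoother then yields the conditional state mean at
    every minute, which fills the gaps. A constant observed channel is a
    degenerate model (q = r = 0) and is filled with the constant directly.
    ``seasonal_period`` optionally adds a stochastic seasonal component (off
    by default; minute-level activity is dominated by local correlation).
    """
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    params: dict[str, dict[str, float]] = {}
    filled: dict[str, np.ndarray] = {}
    for ch in channels:
        y = target.channel(ch)
        obs = ~np.isnan(y)
        if obs.sum() < KALMAN_MIN_OBSERVED:
            raise ValueError(f"channel {ch!r}: need >= {KALMAN_MIN_OBSERVED} observed minutes")
        y_obs = y[obs]
        if np.ptp(y_obs) == 0.0:
            filled[ch] = np.full(len(y), y_obs[0])
            params[ch] = {"level_var": 0.0, "obs_var": 0.0}
            continue
        kwargs = {"level": "local level"}
        if seasonal_period:
            kwargs["seasonal"] = seasonal_period
        model = UnobservedComponents(y, **kwargs)
        res = model.fit(method="lbfgs", maxiter=100, disp=0)
        if not np.isfinite(res.llf):
            raise ValueError(
                f"channel {ch!r}: non-finite likelihood (params={res.params}, "
                f"observed={int(obs.sum())})"
            )
        filled[ch] = np.asarray(res.smoothed_state[0])
        params[ch] = {
            "obs_var": float(res.params[0]),
            "level_var": float(res.params[1]),
        }
    return ImputationResult(_complete(target, filled), "kalman", params=params)


#: Dispatch table used by the evaluation pipelines and the CLI.
METHOD_NAMES = (
    "removal",
    "nohow",
    "overall_mean",
    "individual_mean",
    "overall_mi",
    "individual_mi",
    "random_forest",
    "kalman",
)


def run_method(
    method: str,
    target: ParticipantSeries,
    cohort: list[ParticipantSeries] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    channels: tuple[str, ...] = CHANNELS,
    **kwargs,
) -> ImputationResult:
    """Run one named imputation method (scaling methods are not imputers)."""
    if method == "overall_mean":
        return impute_mean(target, "overall", cohort, channels=channels)
    if method == "individual_mean":
        return impute_mean(target, "individual", channels=channels)
    if method == "overall_mi":
        return impute_multiple_pmm(target, "overall", seed=seed, cohort=cohort, channels=channels, **kwargs)
    if method == "individual_mi":
        return impute_multiple_pmm(target, "individual", seed=seed, channels=channels, **kwargs)
    if method == "random_forest":
        return impute_random_forest(target, seed=seed, channels=channels, **kwargs)
    if method == "kalman":
        return impute_kalman(target, seed=seed, channels=channels, **kwargs)
    raise ValueError(f"unknown imputation method {method!r}")
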