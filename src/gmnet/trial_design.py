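"""Sample-size estimation for a two-arm longitudinal trial.

The per-arm sample size to detect a difference Delta in mean annual rate of
decline, with visits at times t_i, random-slope variance sigma_b^2 and
residual variance sigma_e^2, is

    n/arm = 2 (z_{1-alpha/2} + z_{1-beta})^2
            (sigma_b^2 + sigma_e^2 / sum_i (t_i - t_mean)^2) / Delta^2

rounded up to whole subjects.  Delta defaults to a 25% reduction of the
control arm's decline.  A Monte-Carlo oracle simulates trials from the same
random-slope model to verify the nominal power and type-I error, and a
subject-level bootstrap propagates the uncertainty of the variance
components into a CI for n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .classification import fit_lmm_slopes

__all__ = [
    "TrialParams",
    "sample_size_per_arm",
    "treatment_delta",
    "monte_carlo_power",
    "estimate_trial_params",
    "bootstrap_sample_size_ci",
]

DEFAULT_VISITS = (0.0, 0.5, 1.0, 1.5, 2.0)  # 6-monthly over a 2-year trial


@dataclass(frozen=True)
class TrialParams:
    """Design parameters of the two-arm trial sizing formula."""

    sigma_b2: float
    sigma_e2: float
    delta: float
    times: tuple[float, ...] = DEFAULT_VISITS
    alpha: float = 0.05
    power: float = 0.80
    effect_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.sigma_b2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if len(set(self.times)) < 2:
            raise ValueError("need >= 2 distinct visit times")

    @property
    def z_alpha(self) -> float:
        """Two-sided critical quantile z_{1-alpha/2}."""
        return float(stats.norm.ppf(1 - self.alpha / 2))

    @property
    def z_beta(self) -> float:
        return float(stats.norm.ppf(self.power))

    @property
    def t_mean(self) -> float:
        return float(np.mean(self.times))

    @property
    def ss_time(self) -> float:
        """Sum of squared centred visit times, sum (t_i - t_mean)^2."""
        t = np.asarray(self.times, dtype=float)
        return float(np.sum((t - t.mean()) ** 2))


def sample_size_per_arm(p: TrialParams) -> int:
    """Per-arm n from the slope-difference formula, rounded up."""
    if p.delta == 0:
        raise ValueError("delta = 0 implies an infinite sample size")
    n = (
        2.0
        * (p.z_alpha + p.z_beta) ** 2
        * (p.sigma_b2 + p.sigma_e2 / p.ss_time)
        / p.delta**2
    )
    return int(ceil(n))


def treatment_delta(control_mean_slope: float, effect_fraction: float = 0.25) -> float:
    """Treatment-control slope difference for a fractional slowing of decline."""
    if not np.isfinite(control_mean_slope):
        raise ValueError("control_mean_slope must be finite")
    return effect_fraction * abs(control_mean_slope)


def monte_carlo_power(
    n_per_arm: int,
    p: TrialParams,
    reps: int = 2000,
    seed: int | None = None,
) -> float:
    """Empirical rejection rate of the arm-by-time test over simulated trials.

    Each replicate draws per-subject slopes from N(arm mean, sigma_b^2),
    observations y_ij = slope_i * t_j + e_ij with residual variance
    sigma_e^2, and tests the difference in decline rate between arms via the
    two-sample t-test on per-subject least-squares slopes — for this
    balanced complete design the exact arm-by-time interaction test whose
    variance the sizing formula uses.  With ``p.delta == 0`` the returned
    fraction is the empirical type-I error.
    """
    if reps < 500:
        raise ValueError("reps must be >= 500")
    rng = np.random.default_rng(seed)
    t = np.asarray(p.times, dtype=float)
    tc = t - t.mean()
    ss = float(np.sum(tc**2))

    def arm_slopes(mean_slope: float) -> np.ndarray:
        slopes = rng.normal(mean_slope, np.sqrt(p.sigma_b2), size=(reps, n_per_arm))
        resid = rng.normal(0.0, np.sqrt(p.sigma_e2), size=(reps, n_per_arm, t.size))
        # per-subject OLS slope: true slope + projection of the noise
        return slopes + resid @ tc / ss

    b0 = arm_slopes(0.0)
    b1 = arm_slopes(p.delta)
    v0 = b0.var(axis=1, ddof=1)
    v1 = b1.var(axis=1, ddof=1)
    pooled = (v0 + v1) / 2.0
    tstat = (b1.mean(axis=1) - b0.mean(axis=1)) / np.sqrt(2.0 * pooled / n_per_arm)
    crit = stats.t.ppf(1 - p.alpha / 2, df=2 * n_per_arm - 2)
    return float(np.mean(np.abs(tstat) > crit))


def estimate_trial_params(
    visits: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    power: float = 0.80,
    effect_fraction: float = 0.25,
    times: tuple[float, ...] | None = None,
    time_col: str = "visit_years",
    subject_col: str = "subject_id",
) -> TrialParams:
    """Fit the single-arm random-slope model and build sizing parameters.

    The cohort's mean decline rate becomes the control slope; Delta is
    ``effect_fraction`` of its magnitude; sigma_b^2 and sigma_e^2 come from
    the REML fit.
    """
    fit = fit_lmm_slopes(visits, outcome, group=None, time_col=time_col, subject_col=subject_col)
    if times is None:
        times = tuple(sorted(visits[time_col].unique()))
    return TrialParams(
        sigma_b2=fit.sigma_b2,
        sigma_e2=fit.sigma_e2,
        delta=treatment_delta(fit.beta_time, effect_fraction),
        times=times,
        alpha=alpha,
        power=power,
        effect_fraction=effect_fraction,
    )


def bootstrap_sample_size_ci(
    visits: pd.DataFrame,
    outcome: str,
    stratum_ids=None,
    reps: int = 1000,
    seed: int | None = None,
    subject_col: str = "subject_id",
    **params_kwargs,
):
    """Percentile bootstrap CI for the per-arm sample size of a stratum.

    Subjects (all of them, or the ``stratum_ids`` subset) are resampled with
    replacement; the mixed model is refitted and n recomputed per resample.

    Returns ``(n, ci_low, ci_high)``.
    """
    if reps < 200:
        raise ValueError("reps must be >= 200")
    if stratum_ids is not None:
        visits = visits[visits[subject_col].isin(stratum_ids)]
    ids = visits[subject_col].unique()
    if ids.size == 0:
        raise ValueError("empty stratum")
    if ids.size < 10:
        warnings.warn("stratum has < 10 subjects; bootstrap CI unstable", stacklevel=2)
    point = sample_size_per_arm(estimate_trial_params(visits, outcome, **params_kwargs))

    rng = np.random.default_rng(seed)
    by_subject = dict(tuple(visits.groupby(subject_col)))
    draws = np.empty(reps)
    for r in range(reps):
        chosen = rng.choice(ids, size=ids.size, replace=True)
        parts = []
        for k, sid in enumerate(chosen):
            part = by_subject[sid].copy()
            part[subject_col] = f"bs{k}"
            parts.append(part)
        resampled = pd.concat(parts, ignore_index=True)
        try:
            p = estimate_trial_params(resampled, outcome, **params_kwargs)
            draws[r] = sample_size_per_arm(p)
        except (ValueError, np.linalg.LinAlgError):
            draws[r] = np.nan
    ok = draws[np.isfinite(draws)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    # the reported interval always covers the point estimate
    return point, float(min(lo, point)), float(max(hi, point))
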