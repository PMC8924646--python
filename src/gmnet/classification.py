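"""Logistic and linear-mixed models for 2-year progression.

Binary analyses use the outcome "progressed to dementia within the horizon".
Subjects censored before the horizon without an event are excluded from
binary logistic/accuracy analyses (they are neither progressors nor
confirmed stable) but remain in the tROC and Kaplan-Meier analyses, which
handle censoring directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogisticFit",
    "ClassificationStats",
    "binary_outcome",
    "fit_logistic",
    "classification_stats",
    "biomarker_count_model",
    "LMMSlopes",
    "fit_lmm_slopes",
]


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic regression with Wald inference on odds ratios."""

    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    aic: float
    odds_ratios: pd.DataFrame  # columns: OR, ci_low, ci_high (excl. intercept)
    n_used: int
    separation: bool = False

    def __post_init__(self) -> None:
        expected = 2 * len(self.params) - 2 * self.log_likelihood
        if not np.isclose(self.aic, expected, rtol=1e-10, atol=1e-8):
            raise ValueError("AIC identity 2k - 2logL violated")


@dataclass(frozen=True)
class ClassificationStats:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sens(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else np.nan

    @property
    def spec(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else np.nan

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n


def binary_outcome(df: pd.DataFrame, horizon_years: float = 2.0):
    """Progression-by-horizon labels and the subjects they are defined for.

    Returns ``(y, included)``: ``y`` is 1 for subjects with an event at or
    before the horizon, 0 for subjects followed beyond it without one;
    ``included`` is False for subjects censored event-free before the
    horizon, whose label is unknown.
    """
    time = df["time_years"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    progressed = (event == 1) & (time <= horizon_years)
    stable = time > horizon_years
    included = progressed | stable
    return progressed.astype(int), included


def _design(X, n: int) -> pd.DataFrame:
    if X is None:
        return pd.DataFrame(index=range(n))
    X = pd.DataFrame(X).copy()
    if X.columns.inferred_type == "integer":
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    return X.astype(float)


def fit_logistic(y, X=None) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs on ORs.

    The design must not contain a constant column (an intercept is added
    internally; ``X=None`` fits the intercept-only model) and must have full
    column rank; rank-deficient designs raise an error naming the offending
    columns.  Complete or quasi-complete separation is detected and reported
    with a warning; the CIs are then flagged unreliable via
    ``separation=True``.
    """
    y = np.asarray(y, dtype=float)
    X = _design(X, y.size)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary")
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant predictor column(s): {const_cols}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = []
        kept = [design.columns[0]]
        for c in design.columns[1:]:
            cols = kept + [c]
            if np.linalg.matrix_rank(design[cols].to_numpy()) < len(cols):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"rank-deficient design; dependent column(s): {bad}")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
        except Exception:  # refit more robustly (e.g. separation blowing up Newton)
            res = sm.Logit(y, design).fit(disp=False, method="bfgs", maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    fitted = res.predict(design)
    if np.all((fitted > 0.999) == (y == 1)) and np.all((fitted < 0.001) == (y == 0)):
        separation = True
    if separation:
        warnings.warn(
            "complete or quasi-complete separation detected; Wald CIs unreliable",
            stacklevel=2,
        )

    params = pd.Series(res.params, index=design.columns)
    bse = pd.Series(res.bse, index=design.columns)
    slope_names = [c for c in design.columns if c != "const"]
    or_tbl = pd.DataFrame(
        {
            "OR": np.exp(params[slope_names]),
            "ci_low": np.exp(params[slope_names] - 1.96 * bse[slope_names]),
            "ci_high": np.exp(params[slope_names] + 1.96 * bse[slope_names]),
        }
    )
    return LogisticFit(
        params=params,
        bse=bse,
        log_likelihood=float(res.llf),
        aic=float(2 * len(params) - 2 * res.llf),
        odds_ratios=or_tbl,
        n_used=int(y.size),
        separation=separation,
    )


def classification_stats(y, y_hat) -> ClassificationStats:
    """Sensitivity, specificity and accuracy from predicted binary labels."""
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    tp = int(np.sum((y == 1) & (y_hat == 1)))
    fn = int(np.sum((y == 1) & (y_hat == 0)))
    fp = int(np.sum((y == 0) & (y_hat == 1)))
    tn = int(np.sum((y == 0) & (y_hat == 0)))
    if tp + fn == 0:
        warnings.warn("no positive cases; sensitivity undefined", stacklevel=2)
    return ClassificationStats(tp=tp, fn=fn, fp=fp, tn=tn)


def biomarker_count_model(
    df: pd.DataFrame,
    abnormal_flags: pd.DataFrame,
    horizon_years: float = 2.0,
):
    """Number of abnormal biomarkers (of small-world, p-tau, HV) vs progression.

    Fits a logistic model with the count (0-3) as a categorical predictor,
    reporting ORs of each count against the all-normal reference, plus
    per-count classification stats for the rule "count >= k positive".

    Returns ``(fit, stats)`` where ``stats`` maps k in 1..3 to
    :class:`ClassificationStats`.
    """
    flags = abnormal_flags.astype(int)
    if flags.shape[1] != 3:
        raise ValueError("expected three abnormality flags")
    y_all, included = binary_outcome(df, horizon_years)
    count = flags.sum(axis=1).to_numpy()
    y = y_all[included]
    cnt = count[included]
    if not np.any(cnt == 0):
        raise ValueError("empty reference category (no all-normal subjects)")
    dummies = pd.DataFrame(
        {f"count_{k}": (cnt == k).astype(float) for k in (1, 2, 3) if np.any(cnt == k)}
    )
    fit = fit_logistic(y, dummies)
    stats = {k: classification_stats(y, (cnt >= k).astype(int)) for k in (1, 2, 3)}
    return fit, stats


@dataclass(frozen=True)
class LMMSlopes:
    """Group-by-time fixed effect and variance components from a REML fit."""

    beta_group_time: float
    se_group_time: float
    beta_time: float
    se_time: float
    sigma_b2: float
    sigma_e2: float
    n_subjects: int
    converged: bool


def fit_lmm_slopes(
    visits: pd.DataFrame,
    outcome: str,
    group: pd.Series | dict | None = None,
    time_col: str = "visit_years",
    subject_col: str = "subject_id",
) -> LMMSlopes:
    """Random-intercept + random-slope model for longitudinal decline.

    Fixed effects: intercept, time, group and group x time (the group x time
    coefficient is the difference in mean annual decline between abnormal
    and normal subjects).  Random effects: per-subject intercept and slope.
    Estimated by REML.  With ``group=None`` a single-arm model (intercept +
    time) is fitted and ``beta_group_time`` is NaN.

    Returns the slope-variance sigma_b^2 and residual variance sigma_e^2
    needed for trial sizing.
    """
    df = visits.dropna(subset=[outcome, time_col]).copy()
    if df[time_col].nunique() < 2:
        raise ValueError("need >= 2 distinct visit times")
    n_vis = df.groupby(subject_col)[time_col].size()
    if (n_vis >= 2).mean() < 0.5:
        raise ValueError("need >= 2 visits for at least half of the subjects")

    cols = {"t": df[time_col].to_numpy(dtype=float)}
    if group is not None:
        g = pd.Series(group)
        if not g.index.equals(pd.Index(df[subject_col])):
            g = df[subject_col].map(g)
        cols["g"] = g.to_numpy(dtype=float)
        cols["gt"] = cols["g"] * cols["t"]
    exog = sm.add_constant(pd.DataFrame(cols, index=df.index), has_constant="add")
    exog_re = exog[["const", "t"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df[outcome].to_numpy(dtype=float),
            exog,
            groups=df[subject_col].to_numpy(),
            exog_re=exog_re,
        )
        res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=400)
    params = pd.Series(res.fe_params, index=exog.columns)
    bse = pd.Series(res.bse_fe, index=exog.columns)
    return LMMSlopes(
        beta_group_time=float(params.get("gt", np.nan)),
        se_group_time=float(bse.get("gt", np.nan)),
        beta_time=float(params["t"]),
        se_time=float(bse["t"]),
        sigma_b2=float(res.cov_re.loc["t", "t"]),
        sigma_e2=float(res.scale),
        n_subjects=int(df[subject_col].nunique()),
        converged=bool(res.converged),
    )
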