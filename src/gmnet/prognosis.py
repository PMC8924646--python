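"""Prognostic cut-offs for 2-year progression from censored survival data.

Markers (network metrics gamma/lambda/sigma, CSF p-tau181, TIV-corrected
hippocampal volume) are evaluated with cumulative/dynamic time-dependent ROC
(tROC) curves estimated from censored data by the nearest-neighbour method:
the bivariate survival function S(c, t) = P(X > c, T > t) is estimated by
averaging, over subjects, nearest-neighbour-weighted Kaplan-Meier estimates
of S(t | X = X_i), which yields sensitivity and specificity for the event
"progression by the horizon" at every candidate threshold even when some
subjects are censored before it.

Marker orientation is fixed a priori: disease *lowers* the network metrics
and hippocampal volume (``low_abnormal``) and *raises* p-tau
(``high_abnormal``).  Internally markers are negated as needed so that
larger always means higher risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "MARKER_ORIENTATION",
    "SubjectRecord",
    "TROCCurve",
    "CutoffResult",
    "troc_curve",
    "optimal_cutoff",
    "classify_abnormal",
    "kaplan_meier",
    "default_span",
]

#: Which side of the cut-off is abnormal, fixed by the direction of the
#: disease effect: network metrics and hippocampal volume fall with disease,
#: p-tau rises.
MARKER_ORIENTATION: dict[str, str] = {
    "gamma": "low_abnormal",
    "lambda_": "low_abnormal",
    "sigma": "low_abnormal",
    "hv_norm_ml": "low_abnormal",
    "abeta42_pg_ml": "low_abnormal",
    "ptau_pg_ml": "high_abnormal",
}


@dataclass
class SubjectRecord:
    """One subject's markers, censored outcome and longitudinal scores."""

    subject_id: str
    time_years: float
    event: int
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan
    ptau_pg_ml: float = np.nan
    hv_norm_ml: float = np.nan
    abeta42_pg_ml: float = np.nan
    age_years: float = np.nan
    sex: str | None = None
    education_years: float = np.nan
    scanner_id: str | None = None
    visits: list[tuple[float, float, float]] = field(default_factory=list)
    """(visit_years, mmse, cdr_sb) triples."""

    def __post_init__(self) -> None:
        if not self.time_years > 0:
            raise ValueError("time_years must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_frame(records) -> pd.DataFrame:
    """Coerce a list of SubjectRecord (or a DataFrame) to a cohort table."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        d = {k: v for k, v in vars(r).items() if k != "visits"}
        rows.append(d)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TROCCurve:
    """A time-dependent ROC curve for one marker at one horizon."""

    marker_name: str
    horizon_years: float
    thresholds: np.ndarray  # original marker scale, sorted ascending
    sens_t: np.ndarray
    spec_t: np.ndarray
    auc_t: float
    span: float
    orientation: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_t <= 1.0):
            raise ValueError("auc_t must lie in [0, 1]")


@dataclass(frozen=True)
class CutoffResult:
    """An optimal prognostic cut-off with its operating characteristics."""

    marker_name: str
    cutoff_value: float
    orientation: str
    sens: float
    spec: float
    auc: float


def default_span(n: int) -> float:
    """Nearest-neighbour bandwidth 0.25 * n^(-0.20) (fraction of subjects)."""
    return 0.25 * n ** (-0.20)


def _km_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit estimate of S(t) for one (sub)sample."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = time.size
    s = 1.0
    at_risk = n
    i = 0
    while i < n and time[i] <= t:
        ti = time[i]
        d = 0
        c = 0
        while i < n and time[i] == ti:
            d += event[i]
            c += 1
            i += 1
        if d and at_risk:
            s *= 1.0 - d / at_risk
        at_risk -= c
    return s


def troc_curve(
    records,
    marker_name: str,
    horizon_years: float = 2.0,
    span: float | None = None,
) -> TROCCurve:
    """Cumulative/dynamic tROC for one marker at a horizon.

    ``span`` is the fraction of subjects in each nearest-neighbour window
    (default 0.25*n^-0.2).  Sensitivity and specificity are

        Sens(c, t) = [(1 - F_X(c)) - S(c, t)] / (1 - S(t))
        Spec(c, t) = [S(t) - S(c, t)] / S(t)

    with S(c, t) the nearest-neighbour-smoothed bivariate survival estimate,
    and the AUC is the trapezoidal area under the (1-Spec, Sens) path.
    """
    df = records_to_frame(records)
    sub = df[[marker_name, "time_years", "event"]].dropna(subset=[marker_name])
    x_raw = sub[marker_name].to_numpy(dtype=float)
    time = sub["time_years"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    n = x_raw.size
    if n < 2:
        raise ValueError("need at least 2 subjects with the marker")
    if int(event[time <= horizon_years].sum()) < 2:
        raise ValueError("need >= 2 events before the horizon")
    if span is None:
        span = default_span(n)
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")

    orientation = MARKER_ORIENTATION.get(marker_name, "high_abnormal")
    x = -x_raw if orientation == "low_abnormal" else x_raw.copy()

    # neighbourhoods via the empirical CDF (ties share one rank), window
    # total width = span fraction of subjects
    sorted_x = np.sort(x)
    ranks = np.searchsorted(sorted_x, x, side="right") / n
    half = span / 2.0
    s_i = np.empty(n)
    for i in range(n):
        nb = np.abs(ranks - ranks[i]) <= half
        s_i[i] = _km_at(time[nb], event[nb], horizon_years)

    s_t = s_i.mean()
    if s_t >= 1.0:
        raise ValueError("no estimated risk of the event by the horizon")

    thr = np.unique(x)
    sens = np.empty(thr.size)
    spec = np.empty(thr.size)
    for k, c in enumerate(thr):
        above = x > c
        s_ct = s_i[above].sum() / n
        f_c = np.mean(x <= c)
        sens[k] = ((1.0 - f_c) - s_ct) / (1.0 - s_t)
        spec[k] = (s_t - s_ct) / s_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    # report thresholds on the original marker scale, ascending
    if orientation == "low_abnormal":
        thr_orig = -thr[::-1]
        sens_o, spec_o = sens[::-1], spec[::-1]
    else:
        thr_orig, sens_o, spec_o = thr, sens, spec
    return TROCCurve(
        marker_name=marker_name,
        horizon_years=horizon_years,
        thresholds=thr_orig,
        sens_t=sens_o,
        spec_t=spec_o,
        auc_t=float(np.clip(auc, 0.0, 1.0)),
        span=float(span),
        orientation=orientation,
    )


def optimal_cutoff(curve: TROCCurve) -> CutoffResult:
    """Cut-off maximizing Youden's J = sens + spec - 1.

    Ties are broken toward higher sensitivity (the more inclusive cut).
    """
    j = curve.sens_t + curve.spec_t - 1.0
    if curve.thresholds.size == 1:
        warnings.warn("degenerate marker: single distinct value", stacklevel=2)
    best_j = j.max()
    cand = np.flatnonzero(np.isclose(j, best_j, atol=1e-12))
    k = cand[np.argmax(curve.sens_t[cand])]
    return CutoffResult(
        marker_name=curve.marker_name,
        cutoff_value=float(curve.thresholds[k]),
        orientation=curve.orientation,
        sens=float(curve.sens_t[k]),
        spec=float(curve.spec_t[k]),
        auc=curve.auc_t,
    )


def classify_abnormal(value: float, cutoff: CutoffResult) -> str | None:
    """Label a marker value normal/abnormal; boundary counts as abnormal.

    Returns ``None`` for a missing value.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if not np.isfinite(value):
        raise ValueError("marker value must be finite")
    if cutoff.orientation == "low_abnormal":
        return "abnormal" if value <= cutoff.cutoff_value else "normal"
    return "abnormal" if value >= cutoff.cutoff_value else "normal"


def kaplan_meier(
    records, group_labels, horizon_years: float = 2.0
) -> dict[object, pd.DataFrame]:
    """Per-group Kaplan-Meier survival curves, truncated at the horizon.

    Returns, per group label, a DataFrame with columns ``time``,
    ``survival`` and ``at_risk``.  Empty groups are omitted with a warning.
    """
    df = records_to_frame(records)
    labels = np.asarray(group_labels)
    if labels.size != len(df):
        raise ValueError("group_labels must match the cohort length")
    out: dict[object, pd.DataFrame] = {}
    for g in pd.unique(labels):
        sel = labels == g
        if not sel.any():
            warnings.warn(f"empty group {g!r} omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[sel, "time_years"], df.loc[sel, "event"])
        tbl = kmf.event_table
        times = tbl.index.to_numpy(dtype=float)
        keep = times <= horizon_years
        out[g] = pd.DataFrame(
            {
                "time": times[keep],
                "survival": kmf.survival_function_.to_numpy()[:, 0][keep],
                "at_risk": tbl["at_risk"].to_numpy()[keep],
            }
        )
    return out
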