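"""Time-to-onset analysis: durations, quartiles, Weibull fits, hazard shape.

For every (report, suspected drug) pair on a case report with day-precision
dates, the duration is the number of days from the drug's first prescription
to event onset.  Durations are summarized by quartiles and fitted with a
two-parameter Weibull distribution,

    f(t) = (beta/alpha) * (t/alpha)^(beta-1) * exp(-(t/alpha)^beta),

whose shape parameter carries the hazard information of the Weibull
shape-parameter (WSP) test: shape < 1 with the 95% CI excluding 1 means a
decreasing hazard (early-failure pattern typical of causally related adverse
events), shape ~ 1 a constant background hazard, shape > 1 with the CI
excluding 1 an increasing hazard.  Spontaneous reports contain no at-risk
time, so no censoring model is used.

The maximum-likelihood fit solves the profile score equation for the shape by
safeguarded Newton iteration (the scale has a closed form given the shape);
confidence intervals are Wald on (log scale, log shape) from the observed
information, exponentiated.  Profile-likelihood intervals are available
behind ``ci_method="profile"`` for sensitivity analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .report_store import (
    ROLE_SUSPECTED,
    CaseDefinition,
    ReportDatabase,
    SJS_TEN,
    date_precision,
    normalize_drug_name,
    normalize_drug_names,
)

log = logging.getLogger(__name__)

Z_95 = 1.959964


class HazardClass(str, Enum):
    DECREASING = "decreasing"
    CONSTANT_COMPATIBLE = "constant-compatible"
    INCREASING = "increasing"


@dataclass(frozen=True)
class DurationSummary:
    n: int
    median: float
    lower_quartile: float
    upper_quartile: float
    minimum: float
    maximum: float


@dataclass
class WeibullFit:
    scale: float          # alpha, days
    shape: float          # beta, dimensionless
    scale_ci: tuple[float, float]
    shape_ci: tuple[float, float]
    n: int
    loglik: float
    converged: bool


def compute_durations(
    db: ReportDatabase,
    drug_names: Iterable[str],
    case_def: CaseDefinition = SJS_TEN,
    role_code: str = ROLE_SUSPECTED,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drug-to-onset durations for case reports, with an exclusion ledger.

    For each (report, drug) pair where the drug has the required role and a
    day-precision start date, and the report has a day-precision onset date
    for a case-defining preferred term: duration = onset - earliest start, in
    whole days.  Only day-precision dates qualify; month/year-precision and
    missing dates are excluded and counted.  When a report carries several
    qualifying event onsets the earliest is kept (the extras are counted).
    Negative durations (onset before first prescription) are excluded and
    counted.  Returns ``(durations, exclusions)`` where durations has columns
    report_id, drug_name, duration_days.
    """
    names = normalize_drug_names(drug_names)
    excl = {
        "incomplete_start_date": 0,
        "incomplete_onset_date": 0,
        "extra_events_collapsed": 0,
        "negative_duration": 0,
    }

    dd = db.drug.loc[db.drug["role_code"] == role_code].copy()
    dd["name"] = dd["drug_name"].map(normalize_drug_name)
    dd = dd.loc[dd["name"].isin(names)]
    if not dd.empty:
        prec = dd["start_date"].map(date_precision)
        excl["incomplete_start_date"] = int((prec != "day").sum())
        dd = dd.loc[prec == "day"].copy()
        dd["start"] = pd.to_datetime(dd["start_date"], format="%Y-%m-%d")
        starts = dd.groupby(["report_id", "name"], as_index=False)["start"].min()
    else:
        starts = pd.DataFrame(columns=["report_id", "name", "start"])

    rr = db.reac.loc[db.reac["pt_code"].isin(case_def.pt_codes)].copy()
    if not rr.empty:
        prec = rr["onset_date"].map(date_precision)
        excl["incomplete_onset_date"] = int((prec != "day").sum())
        rr = rr.loc[prec == "day"].copy()
        rr["onset"] = pd.to_datetime(rr["onset_date"], format="%Y-%m-%d")
        n_events = len(rr)
        onsets = rr.groupby("report_id", as_index=False)["onset"].min()
        excl["extra_events_collapsed"] = n_events - len(onsets)
    else:
        onsets = pd.DataFrame(columns=["report_id", "onset"])

    merged = starts.merge(onsets, on="report_id", how="inner")
    if merged.empty:
        log.info("no complete (start, onset) combinations for %s", sorted(names))
        return (
            pd.DataFrame(columns=["report_id", "drug_name", "duration_days"]),
            excl,
        )
    merged["duration_days"] = (merged["onset"] - merged["start"]).dt.days.astype(float)
    neg = merged["duration_days"] < 0
    excl["negative_duration"] = int(neg.sum())
    merged = merged.loc[~neg]
    out = merged.rename(columns={"name": "drug_name"})[
        ["report_id", "drug_name", "duration_days"]
    ].reset_index(drop=True)
    return out, excl


def summarize(durations: Iterable[float]) -> DurationSummary:
    """Median, quartiles and range of a duration sample.

    Quartiles use the inclusive (n+1)-position rule with linear
    interpolation, so e.g. [1, 2, 3, 8, 20] gives Q1 = 1.5 and Q3 = 14.
    """
    t = np.asarray(list(durations), dtype=float)
    if t.size == 0:
        raise ValueError("cannot summarize an empty duration sample")
    q1, med, q3 = np.percentile(t, [25, 50, 75], method="weibull")
    return DurationSummary(
        n=int(t.size),
        median=float(med),
        lower_quartile=float(q1),
        upper_quartile=float(q3),
        minimum=float(t.min()),
        maximum=float(t.max()),
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood


def _weibull_loglik(t: np.ndarray, scale: float, shape: float) -> float:
    n = t.size
    s = np.log(t)
    z = (t / scale) ** shape
    return float(
        n * math.log(shape)
        - n * shape * math.log(scale)
        + (shape - 1.0) * s.sum()
        - z.sum()
    )


def _profile_score(shape: float, s: np.ndarray) -> float:
    """Score equation in the shape with the scale profiled out.

    s = log durations.  Stable for large shapes via max-shift weights.
    """
    m = s.max()
    w = np.exp(shape * (s - m))
    return 1.0 / shape + s.mean() - float((w @ s) / w.sum())


def _profile_score_deriv(shape: float, s: np.ndarray) -> float:
    m = s.max()
    w = np.exp(shape * (s - m))
    sw = w.sum()
    mean_s = float((w @ s) / sw)
    mean_s2 = float((w @ s**2) / sw)
    return -1.0 / shape**2 - (mean_s2 - mean_s**2)


def _solve_shape(s: np.ndarray, tol: float) -> tuple[float, bool]:
    """Safeguarded Newton on the profile score (monotone decreasing)."""
    lo, hi = 1e-3, 1e3
    g_lo, g_hi = _profile_score(lo, s), _profile_score(hi, s)
    if g_lo < 0 or g_hi > 0:
        raise ValueError(
            "profile score has no sign change: degenerate duration sample "
            "(all values equal?)"
        )
    shape = 1.0
    converged = False
    for _ in range(200):
        g = _profile_score(shape, s)
        if abs(g) < tol:
            converged = True
            break
        if g > 0:
            lo = shape
        else:
            hi = shape
        step = g / _profile_score_deriv(shape, s)
        cand = shape - step
        if not (lo < cand < hi):
            cand = 0.5 * (lo + hi)  # bisection safeguard
        shape = cand
    return shape, converged


def _profiled_scale(s: np.ndarray, shape: float) -> float:
    m = s.max()
    w = np.exp(shape * (s - m))
    return math.exp(m + math.log(w.mean()) / shape)


def _observed_information_log(t: np.ndarray, scale: float, shape: float) -> np.ndarray:
    """Observed information for (log scale, log shape) at the MLE.

    Analytic second derivatives of the log-likelihood in (scale, shape),
    transformed with the chain rule; the first-derivative terms vanish at the
    optimum.
    """
    n = t.size
    z = (t / scale) ** shape
    u = np.log(t / scale)
    S = z.sum()
    ll_aa = -(shape / scale**2) * (S - n) - (shape**2 / scale**2) * S
    ll_ab = (S - n) / scale + (shape / scale) * float(z @ u)
    ll_bb = -n / shape**2 - float(z @ u**2)
    H = np.array(
        [
            [scale**2 * ll_aa, scale * shape * ll_ab],
            [scale * shape * ll_ab, shape**2 * ll_bb],
        ]
    )
    return -H


def _profile_ci(
    t: np.ndarray, scale_hat: float, shape_hat: float, ll_max: float, which: str
) -> tuple[float, float]:
    """Profile-likelihood 95% CI by root-finding on the profile deviance."""
    s = np.log(t)
    crit = ll_max - stats.chi2.ppf(0.95, 1) / 2.0

    if which == "shape":
        def pl(b: float) -> float:
            return _weibull_loglik(t, _profiled_scale(s, b), b)
        center = shape_hat
    else:
        def pl(a: float) -> float:
            # maximize over shape for fixed scale a via the 1-D score in shape
            def score(b: float) -> float:
                z = (t / a) ** b
                u = np.log(t / a)
                return t.size / b + u.sum() - float(z @ u)
            lo, hi = 1e-3, 1e3
            if score(lo) < 0 or score(hi) > 0:
                return -np.inf
            b = optimize.brentq(score, lo, hi, xtol=1e-10)
            return _weibull_loglik(t, a, b)
        center = scale_hat

    def dev(x: float) -> float:
        return pl(x) - crit

    lo_bound = center
    step = center * 0.05
    while dev(lo_bound) > 0 and lo_bound > center * 1e-3:
        lo_bound = max(lo_bound - step, center * 1e-3)
        step *= 1.6
    low = optimize.brentq(dev, lo_bound, center, xtol=1e-8) if dev(lo_bound) < 0 else lo_bound
    hi_bound = center
    step = center * 0.05
    while dev(hi_bound) > 0 and hi_bound < center * 1e3:
        hi_bound = min(hi_bound + step, center * 1e3)
        step *= 1.6
    high = optimize.brentq(dev, center, hi_bound, xtol=1e-8) if dev(hi_bound) < 0 else hi_bound
    return float(low), float(high)


def fit_weibull(
    durations: Iterable[float],
    tol: float = 1e-10,
    min_n: int = 10,
    zero_shift: float = 0.5,
    ci_method: str = "wald",
    z: float = Z_95,
) -> WeibullFit:
    """Two-parameter Weibull maximum-likelihood fit of a duration sample.

    Zero durations (same-day onset, legitimately reported) are replaced by
    ``zero_shift`` days before fitting, since the log-density is undefined at
    zero; descriptive statistics elsewhere keep the raw zeros.  Samples
    smaller than ``min_n`` are refused; between ``min_n`` and 100 a warning
    is emitted (small-sample Weibull estimates deserve caution).
    """
    t = np.asarray(list(durations), dtype=float)
    if np.any(t < 0):
        raise ValueError("durations must be non-negative")
    if t.size < min_n:
        raise ValueError(
            f"need at least {min_n} durations for a Weibull fit, got {t.size}"
        )
    if t.size < 100:
        warnings.warn(
            f"Weibull fit on only {t.size} durations; interpret cautiously",
            stacklevel=2,
        )
    t = np.where(t == 0.0, zero_shift, t)
    s = np.log(t)

    shape, converged = _solve_shape(s, tol)
    scale = _profiled_scale(s, shape)
    ll = _weibull_loglik(t, scale, shape)

    info = _observed_information_log(t, scale, shape)
    cov = np.linalg.inv(info)
    se_log = np.sqrt(np.diag(cov))
    if ci_method == "wald":
        scale_ci = (scale * math.exp(-z * se_log[0]), scale * math.exp(z * se_log[0]))
        shape_ci = (shape * math.exp(-z * se_log[1]), shape * math.exp(z * se_log[1]))
    elif ci_method == "profile":
        scale_ci = _profile_ci(t, scale, shape, ll, "scale")
        shape_ci = _profile_ci(t, scale, shape, ll, "shape")
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")

    return WeibullFit(
        scale=scale,
        shape=shape,
        scale_ci=scale_ci,
        shape_ci=shape_ci,
        n=int(t.size),
        loglik=ll,
        converged=converged,
    )


def fit_exponential_scale(durations: Iterable[float], zero_shift: float = 0.5) -> float:
    """Scale MLE with the shape fixed at 1 (exponential): the sample mean."""
    t = np.asarray(list(durations), dtype=float)
    t = np.where(t == 0.0, zero_shift, t)
    return float(t.mean())


def classify_hazard(fit: WeibullFit) -> HazardClass:
    """WSP hazard call from the shape estimate and its 95% CI.

    Increasing/decreasing requires the CI to *exclude* 1 — a bound touching
    1.00 is still compatible with a constant hazard.
    """
    if not fit.converged:
        raise ValueError("cannot classify a non-convergent Weibull fit")
    lo, hi = fit.shape_ci
    if fit.shape > 1.0 and lo > 1.0:
        return HazardClass.INCREASING
    if fit.shape < 1.0 and hi < 1.0:
        return HazardClass.DECREASING
    return HazardClass.CONSTANT_COMPATIBLE


def onset_histogram(
    durations: Iterable[float],
    bin_width: int = 1,
    t_max: int = 56,
) -> pd.DataFrame:
    """Day-binned onset counts over [0, t_max] plus an overflow bin.

    Returns a DataFrame with columns ``day`` (bin left edge as string, the
    overflow labelled ``">{t_max}"``) and ``count``.
    """
    t = np.asarray(list(durations), dtype=float)
    edges = np.arange(0, t_max + bin_width, bin_width)
    counts = {int(e): 0 for e in edges}
    overflow = 0
    for v in t:
        if v > t_max:
            overflow += 1
        else:
            counts[int(v // bin_width) * bin_width] += 1
    rows = [{"day": str(e), "count": counts[int(e)]} for e in edges]
    rows.append({"day": f">{t_max}", "count": overflow})
    return pd.DataFrame(rows)


class WeibullOnsetModel(BaseEstimator):
    """Scikit-learn style estimator for the Weibull time-to-onset fit.

    ``fit`` takes a 1-D array of durations in days.  Fitted attributes:
    ``scale_``, ``shape_``, ``scale_ci_``, ``shape_ci_``, ``loglik_``,
    ``n_``, ``converged_``, ``hazard_class_``.
    """

    def __init__(
        self,
        tol: float = 1e-10,
        min_n: int = 10,
        zero_shift: float = 0.5,
        ci_method: str = "wald",
        z: float = Z_95,
    ):
        self.tol = tol
        self.min_n = min_n
        self.zero_shift = zero_shift
        self.ci_method = ci_method
        self.z = z

    def fit(self, X, y=None) -> "WeibullOnsetModel":
        t = np.asarray(X, dtype=float).ravel()
        res = fit_weibull(
            t,
            tol=self.tol,
            min_n=self.min_n,
            zero_shift=self.zero_shift,
            ci_method=self.ci_method,
            z=self.z,
        )
        self.result_ = res
        self.scale_ = res.scale
        self.shape_ = res.shape
        self.scale_ci_ = res.scale_ci
        self.shape_ci_ = res.shape_ci
        self.loglik_ = res.loglik
        self.n_ = res.n
        self.converged_ = res.converged
        self.hazard_class_ = classify_hazard(res)
        return self

    def survival_function(self, times) -> np.ndarray:
        """S(t) = exp(-(t/scale)^shape) at the fitted parameters."""
        t = np.asarray(times, dtype=float)
        return np.exp(-((t / self.scale_) ** self.shape_))
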