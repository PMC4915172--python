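"""Age-, gender- and reporting-year-adjusted reporting odds ratios.

Case status is modelled by logistic regression,

    log(odds) = b0 + b1*Y + b2*G + b3*A,

where Y is the reporting year (one linear term, offset by the base year for
conditioning), G indicates female gender, and A is the age stratum coded as
four indicators with the 40-59-year group as reference.  Exponentiated
coefficients are the adjusted RORs; each term is additionally tested with a
likelihood-ratio test against the model without that column (chi-square,
1 df).  The same machinery runs on drug-exposed subsets of the database to
give intraclass (subset) adjusted RORs.

Estimation is plain Newton-Raphson/IRLS maximum likelihood written here so
that its convergence rules are explicit; statsmodels reproduces it and is
used as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .report_store import ANALYSIS_STRATA, AgeStratum, subset_by_drug

log = logging.getLogger(__name__)

Z_95 = 1.959964

#: Non-reference strata, in reporting order.
STRATUM_TERMS: tuple[AgeStratum, ...] = (
    AgeStratum.LE19,
    AgeStratum.Y20_39,
    AgeStratum.Y60_79,
    AgeStratum.GE80,
)

TERM_LABELS: dict[str, str] = {
    "reporting_year": "Reporting year",
    "female": "Gender female",
    "age_le19": "Age <=19 years",
    "age_20_39": "Age 20-39 years",
    "age_60_79": "Age 60-79 years",
    "age_ge80": "Age >=80 years",
}


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges (perfect separation)."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    names: list[str]

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def build_design(
    ds: pd.DataFrame,
    base_year: int = 2004,
    reference: AgeStratum = AgeStratum.Y40_59,
) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix and outcome vector for the adjustment model.

    Returns ``(X, y, names, info)`` where X has an intercept column, the
    year term coded as (reporting_year - base_year), the female indicator and
    four stratum indicators (reference stratum all-zero).  Rows with missing
    reporting year are dropped (the model uses Y); indicator columns with no
    variation — an empty stratum, a single-sex dataset — are dropped with a
    warning rather than producing a singular fit, and are listed in
    ``info["dropped"]``.
    """
    keep = ds["reporting_year"].notna()
    n_dropped_year = int((~keep).sum())
    if n_dropped_year:
        log.info("dropping %d reports with missing reporting year from the model",
                 n_dropped_year)
    sub = ds.loc[keep]
    if sub.empty:
        raise ValueError("no reports with a known reporting year")

    y = sub["is_case"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sub)),
        "reporting_year": sub["reporting_year"].to_numpy(dtype=float) - base_year,
        "female": (sub["sex"] == "female").to_numpy(dtype=float),
    }
    strat_names = {
        AgeStratum.LE19: "age_le19",
        AgeStratum.Y20_39: "age_20_39",
        AgeStratum.Y40_59: "age_40_59",
        AgeStratum.Y60_79: "age_60_79",
        AgeStratum.GE80: "age_ge80",
    }
    for st in ANALYSIS_STRATA:
        if st == reference:
            continue
        cols[strat_names[st]] = (sub["age_stratum"] == st.value).to_numpy(dtype=float)

    dropped = []
    for name in list(cols):
        if name == "intercept":
            continue
        if np.ptp(cols[name]) == 0.0:
            warnings.warn(
                f"design column '{name}' has no variation and was dropped",
                stacklevel=2,
            )
            dropped.append(name)
            del cols[name]
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    info = {
        "base_year": base_year,
        "reference": reference.value,
        "dropped": dropped,
        "n_dropped_missing_year": n_dropped_year,
        "coding": "year = reporting_year - base_year; female = 1; "
                  f"stratum indicators vs reference {reference.value}",
    }
    return X, y, names, info


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    names: Sequence[str] | None = None,
) -> LogisticFit:
    """Newton-Raphson (IRLS) maximum-likelihood logistic regression.

    Convergence when the score sup-norm falls below ``tol`` or the relative
    log-likelihood change does; covariance is the inverse observed information
    at the optimum.  Step-halving keeps the log-likelihood non-decreasing.
    Diverging coefficients (|beta| > 35) signal perfect separation and raise
    :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome")
    if y.min() < 0 or y.max() > 1:
        raise ValueError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has no variation (all cases or no cases)")

    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                "singular information matrix; data may be separated or the "
                "design rank-deficient"
            ) from err
        # step-halving: never accept a step that lowers the log-likelihood
        new_ll = _loglik(X, y, beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_ll = _loglik(X, y, beta + step)
            halvings += 1
        beta = beta + step
        if np.max(np.abs(beta)) > 35.0:
            raise SeparationError(
                "coefficients diverging (|beta| > 35): perfect separation"
            )
        # stagnation exit well below the score tolerance, so the score
        # criterion (and with it near-exact MLEs) normally governs
        if abs(new_ll - ll) < 1e-4 * tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    if not converged:
        warnings.warn("fit_logistic did not converge; CIs unreliable", stacklevel=2)
    return LogisticFit(
        beta=beta,
        cov=cov,
        loglik=_loglik(X, y, beta),
        n=n,
        converged=converged,
        n_iter=it,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
    )


def adjusted_ror_table(fit: LogisticFit, z: float = Z_95) -> pd.DataFrame:
    """One row per non-intercept term: beta, SE, adjusted ROR and Wald CI."""
    if not fit.converged:
        raise ValueError("fit did not converge; adjusted RORs suppressed")
    se = fit.se()
    rows = []
    for j, name in enumerate(fit.names):
        if name == "intercept":
            continue
        rows.append(
            dict(
                term=name,
                label=TERM_LABELS.get(name, name),
                beta=fit.beta[j],
                se=se[j],
                adjusted_ror=float(np.exp(fit.beta[j])),
                ci_low=float(np.exp(fit.beta[j] - z * se[j])),
                ci_high=float(np.exp(fit.beta[j] + z * se[j])),
            )
        )
    return pd.DataFrame(rows)


def lrt_term(
    X: np.ndarray,
    y: np.ndarray,
    fit_full: LogisticFit,
    term: int | str,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Likelihood-ratio test for one term: drop its column and refit.

    Returns ``(statistic, p)`` with the statistic 2*(ll_full - ll_reduced)
    referred to chi-square with one degree of freedom.  A non-convergent
    reduced fit yields ``(nan, nan)``.
    """
    j = fit_full.names.index(term) if isinstance(term, str) else int(term)
    if fit_full.names[j] == "intercept":
        raise ValueError("cannot LRT the intercept")
    X_red = np.delete(np.asarray(X, dtype=float), j, axis=1)
    names_red = [nm for k, nm in enumerate(fit_full.names) if k != j]
    try:
        fit_red = fit_logistic(X_red, y, tol=tol, max_iter=max_iter, names=names_red)
    except SeparationError:
        return float("nan"), float("nan")
    if not fit_red.converged:
        return float("nan"), float("nan")
    stat = 2.0 * (fit_full.loglik - fit_red.loglik)
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df=1))


class AdjustedRorModel(BaseEstimator):
    """Scikit-learn style estimator for the adjusted-ROR logistic model.

    ``fit`` accepts the analysis dataset (one row per report with sex,
    age_stratum, reporting_year and is_case columns); the outcome defaults to
    the dataset's ``is_case`` flag.

    Parameters
    ----------
    base_year : year subtracted from reporting_year before fitting.
    reference : the reference age stratum (default 40-59 years).
    tol, max_iter : Newton-Raphson controls.
    z : normal quantile for the Wald CIs (default two-sided 95%).

    Attributes (after fit)
    ----------------------
    coef_, cov_, loglik_, converged_, n_iter_ : the logistic fit.
    feature_names_ : design column names including the intercept.
    summary_ : DataFrame of adjusted RORs, Wald CIs and LRT p-values.
    """

    def __init__(
        self,
        base_year: int = 2004,
        reference: AgeStratum = AgeStratum.Y40_59,
        tol: float = 1e-8,
        max_iter: int = 100,
        z: float = Z_95,
    ):
        self.base_year = base_year
        self.reference = reference
        self.tol = tol
        self.max_iter = max_iter
        self.z = z

    def fit(self, X: pd.DataFrame, y=None) -> "AdjustedRorModel":
        ds = X
        design, outcome, names, info = build_design(
            ds, base_year=self.base_year, reference=self.reference
        )
        if y is not None:
            outcome = np.asarray(y, dtype=float)[ds["reporting_year"].notna()]
        fit = fit_logistic(design, outcome, tol=self.tol,
                           max_iter=self.max_iter, names=names)
        self.fit_ = fit
        self.design_info_ = info
        self.coef_ = fit.beta
        self.cov_ = fit.cov
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.feature_names_ = fit.names
        table = adjusted_ror_table(fit, z=self.z)
        pvals = {}
        for term in table["term"]:
            _, p = lrt_term(design, outcome, fit, term,
                            tol=self.tol, max_iter=self.max_iter)
            pvals[term] = p
        table["lrt_p"] = table["term"].map(pvals)
        table["significant"] = table["lrt_p"] <= 0.05
        self.summary_ = table
        return self

    def predict_proba_dataset(self, ds: pd.DataFrame) -> np.ndarray:
        """Fitted case probability for each row of an analysis dataset."""
        design, _, names, _ = build_design(
            ds, base_year=self.base_year, reference=self.reference
        )
        if names != self.feature_names_:
            raise ValueError("dataset design columns differ from the fitted design")
        return expit(design @ self.coef_)


def run_adjusted_analysis(
    ds: pd.DataFrame,
    drug_sets: Mapping[str, Iterable[str]],
    base_year: int = 2004,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict[str, pd.DataFrame]:
    """Whole-data block plus one block per drug / drug group subset.

    Each block is the adjusted-ROR table (term, beta, adjusted ROR, Wald CI,
    LRT p).  Subsets without outcome variation, or whose fit separates, are
    skipped with a warning rather than aborting the whole analysis.
    """
    blocks: dict[str, pd.DataFrame] = {}
    model = AdjustedRorModel(base_year=base_year, tol=tol, max_iter=max_iter)
    blocks["whole"] = model.fit(ds).summary_
    for label, names in drug_sets.items():
        try:
            sub = subset_by_drug(ds, names)
            ncase = int(sub["is_case"].sum())
            if ncase == 0 or ncase == len(sub):
                raise ValueError("no outcome variation in subset")
            blocks[label] = AdjustedRorModel(
                base_year=base_year, tol=tol, max_iter=max_iter
            ).fit(sub).summary_
        except (ValueError, SeparationError) as err:
            log.warning("subset block '%s' skipped: %s", label, err)
    return blocks
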