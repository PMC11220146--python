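"""Survival statistics: Kaplan-Meier, log-rank, minimum-p cutpoint, Cox PH.

Clinical tables are pandas DataFrames with mandatory columns
``time_months`` (> 0) and ``event`` (1 = death) plus arbitrary covariate
columns.  Estimation is delegated to lifelines (product-limit estimator,
log-rank with hypergeometric variance, Efron partial likelihood for tied
event times); the minimum-p-value dichotomization of a continuous marker
and the subgroup interaction contrast are built on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

TIME_COL = "time_months"
EVENT_COL = "event"


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records)
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise ValueError(f"records must have a {col!r} column")
    if (df[TIME_COL] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df[EVENT_COL].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df


@dataclass
class KMEstimate:
    """Product-limit survival curve and median survival time."""

    curve: pd.DataFrame          # columns: time, survival
    median_months: float         # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        c = self.curve
        below = c[c["time"] <= t]
        return float(below["survival"].iloc[-1]) if len(below) else 1.0


@dataclass
class CutpointResult:
    """Minimum-p-value dichotomization of a continuous marker."""

    cutoff: float
    p_value: float
    scan: pd.DataFrame           # columns: cutoff, p
    minprop: float


@dataclass
class CoxResult:
    """Tidy Cox proportional-hazards fit."""

    table: pd.DataFrame          # term, coef, HR, CI_low, CI_high, se, p
    log_likelihood: float
    ties: str
    monotone_likelihood: bool = False

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "HR"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier curve; median = earliest time with S(t) <= 0.5."""
    df = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df[TIME_COL], df[EVENT_COL])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    return KMEstimate(curve, median)


def logrank_test(records: pd.DataFrame, groups) -> tuple:
    """Log-rank test across >= 2 groups: returns (chi2, df, p)."""
    df = _check_records(records)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if df[EVENT_COL].sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    res = multivariate_logrank_test(df[TIME_COL], g, df[EVENT_COL])
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def optimal_cutpoint(marker, records: pd.DataFrame,
                     minprop: float = 0.1) -> CutpointResult:
    """Minimum-p-value dichotomization of a continuous marker.

    Candidate cutoffs are the midpoints of adjacent sorted unique marker
    values whose induced split leaves at least ``minprop`` of patients on
    each side; the two-group log-rank p is evaluated at every candidate and
    the argmin returned (ties toward the lower cutoff).  The naive minimal
    p is reported without multiplicity adjustment.
    """
    df = _check_records(records)
    m = np.asarray(marker, dtype=float)
    if len(m) != len(df):
        raise ValueError("marker and records length mismatch")
    uniq = np.unique(m)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct marker values")
    n = len(m)
    cands = [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])
             if minprop * n <= np.sum(m > (a + b) / 2) <= (1 - minprop) * n]
    if not cands:
        raise ValueError("no candidate cutoff satisfies the minprop constraint")
    rows = []
    for c in cands:
        high = (m > c).astype(int)
        chi2, _, p = logrank_test(df, high)
        rows.append({"cutoff": float(c), "p": p})
    scan = pd.DataFrame(rows)
    best = scan.loc[scan["p"].idxmin()]  # idxmin returns first (lowest cutoff) tie
    return CutpointResult(float(best["cutoff"]), float(best["p"]), scan, minprop)


def cox_fit(records: pd.DataFrame, covariates: list,
            ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling by default).

    The partial likelihood is maximized by Newton-Raphson; Wald 95% CIs are
    exp(coef +/- 1.96 SE).  A monotone likelihood (infinite coefficient) is
    detected via diverging coefficients and flagged.
    """
    df = _check_records(records)
    if df[EVENT_COL].sum() < 1:
        raise ValueError("need at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    exog = df[list(covariates)].astype(float)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = PHReg(df[TIME_COL].astype(float), exog,
                  status=df[EVENT_COL].astype(int), ties=ties)
    res = model.fit()
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    table = pd.DataFrame({
        "term": list(covariates),
        "coef": coef,
        "HR": np.exp(coef),
        "CI_low": np.exp(coef - 1.96 * se),
        "CI_high": np.exp(coef + 1.96 * se),
        "se": se,
        "p": np.asarray(res.pvalues),
    })
    monotone = bool(np.any(np.abs(coef) > 20))
    if monotone:
        logger.warning("possible monotone likelihood: |coef| > 20")
    return CoxResult(table, float(res.model.loglike(res.params)), ties, monotone)


def subgroup_interaction(records: pd.DataFrame, marker_col: str,
                         subgroup_col: str) -> tuple:
    """Wald p of the marker x subgroup product term in a Cox model.

    Both variables are coded as 0/1 dummies (reference = lexicographically
    first level); every marker-by-subgroup cell must be non-empty.

    Returns (interaction p, CoxResult of the model with main effects and
    the product term).
    """
    df = _check_records(records).copy()
    coded = {}
    for col in (marker_col, subgroup_col):
        levels = sorted(pd.unique(df[col]))
        if len(levels) != 2:
            raise ValueError(f"{col!r} must be binary, got levels {levels}")
        coded[col] = (df[col] == levels[1]).astype(float)
    cells = pd.crosstab(coded[marker_col], coded[subgroup_col])
    if cells.shape != (2, 2) or (cells == 0).any().any():
        empty = [(int(i), int(j)) for i in (0, 1) for j in (0, 1)
                 if i not in cells.index or j not in cells.columns
                 or cells.loc[i, j] == 0]
        raise ValueError(f"empty marker x subgroup cell(s): {empty}")
    df["_marker"] = coded[marker_col]
    df["_subgroup"] = coded[subgroup_col]
    df["_interaction"] = df["_marker"] * df["_subgroup"]
    res = cox_fit(df, ["_marker", "_subgroup", "_interaction"])
    return res.p("_interaction"), res
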