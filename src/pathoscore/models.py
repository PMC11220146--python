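"""Pathomics-score models: logistic regression and linear SVM.

The logistic model is fit by maximum likelihood (Newton iterations) and
reduced by backward stepwise elimination on the Akaike information
criterion, AIC = 2k - 2 ln L.  The SVM is a linear soft-margin classifier
whose decision values are mapped to probabilities by Platt scaling fit on
out-of-fold decision values.  Either way the pathomics score (PS) of a
patient is the model's predicted probability of the high-expression class,
a number in [0, 1]; "high expression" is the positive class (label 1)
throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_SVM_C = 1.0
PLATT_FOLDS = 5


@dataclass
class PathomicsModel:
    """A fitted pathomics-score model.

    ``predictor`` maps a feature DataFrame (standardized with training
    parameters) to the probability of the high-expression class.
    """

    kind: str                    # "lr" | "svm"
    feature_names: list
    predictor: object = field(repr=False)
    coefficients: pd.Series | None = None
    intercept: float | None = None
    aic: float | None = None
    log_likelihood: float | None = None
    penalized_fallback: bool = False
    metadata: dict = field(default_factory=dict)

    def score(self, X: pd.DataFrame) -> pd.Series:
        return pathomics_score(self, X)


def _check_xy(X: pd.DataFrame, y) -> tuple:
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


def fit_logistic(X: pd.DataFrame, y) -> PathomicsModel:
    """Maximum-likelihood logistic regression with intercept.

    Newton iterations to log-likelihood convergence (tolerance 1e-8, at
    most 100 iterations).  Perfect separation is detected (diverging
    weights) and reported via a ridge-penalized fallback fit with
    ``penalized_fallback=True``.
    """
    X, y = _check_xy(X, y)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need n > number of features + 1")
    design = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, design).fit(disp=0, method="newton",
                                          maxiter=100, tol=1e-8)
        separated = (
            any("separation" in str(w.message).lower() for w in caught)
            or bool(np.any(np.abs(res.params.iloc[1:]) > 50))
            or not np.all(np.isfinite(res.bse))
        )
    except Exception:
        res, separated = None, True
    if separated:
        logger.warning("perfect separation detected; using penalized fallback")
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(), y)
        coefs = pd.Series(clf.coef_.ravel(), index=X.columns)
        intercept = float(clf.intercept_[0])
        return PathomicsModel(
            kind="lr", feature_names=list(X.columns), predictor=("linear", coefs, intercept),
            coefficients=coefs, intercept=intercept, penalized_fallback=True,
        )
    coefs = pd.Series(res.params.iloc[1:].to_numpy(), index=X.columns)
    intercept = float(res.params.iloc[0])
    return PathomicsModel(
        kind="lr", feature_names=list(X.columns),
        predictor=("linear", coefs, intercept),
        coefficients=coefs, intercept=intercept,
        aic=float(res.aic), log_likelihood=float(res.llf),
    )


def backward_stepwise_aic(X: pd.DataFrame, y,
                          model: PathomicsModel | None = None) -> PathomicsModel:
    """Backward stepwise elimination on AIC from the full logistic model.

    At each step the single feature whose removal most decreases
    AIC = 2k - 2 ln L is dropped; the procedure stops when no removal
    decreases AIC.  The intercept is never dropped.
    """
    X, y = _check_xy(X, y)
    current = model if model is not None else fit_logistic(X, y)
    features = list(current.feature_names)
    while len(features) > 1:
        best_drop, best_aic = None, current.aic
        for f in features:
            trial = fit_logistic(X[[g for g in features if g != f]], y)
            if trial.aic is not None and trial.aic < best_aic:
                best_drop, best_aic = f, trial.aic
        if best_drop is None:
            break
        features.remove(best_drop)
        current = fit_logistic(X[features], y)
        logger.info("stepwise dropped %s (AIC %.3f)", best_drop, current.aic)
    return current


def fit_svm(X: pd.DataFrame, y, C: float = DEFAULT_SVM_C, kernel: str = "linear",
            platt_folds: int = PLATT_FOLDS) -> PathomicsModel:
    """Linear soft-margin SVM with Platt-scaled probabilities.

    The decision function minimizes hinge loss + L2 penalty; probabilities
    come from a sigmoid (Platt) calibration fit on out-of-fold decision
    values over ``platt_folds`` stratified folds.
    """
    X, y = _check_xy(X, y)
    base = SVC(kernel=kernel, C=C)
    min_class = int(np.bincount(y.astype(int)).min())
    folds = min(platt_folds, min_class)
    if folds < platt_folds:
        logger.info("Platt folds reduced to %d (smallest class size)", folds)
    calibrated = CalibratedClassifierCV(base, method="sigmoid", cv=folds)
    calibrated.fit(X.to_numpy(), y)
    coefs, intercept = None, None
    if kernel == "linear":
        raw = SVC(kernel="linear", C=C).fit(X.to_numpy(), y)
        coefs = pd.Series(raw.coef_.ravel(), index=X.columns)
        intercept = float(raw.intercept_[0])
    return PathomicsModel(
        kind="svm", feature_names=list(X.columns), predictor=("sklearn", calibrated),
        coefficients=coefs, metadata={"C": C, "kernel": kernel,
                                      "platt_folds": platt_folds,
                                      "intercept": intercept},
    )


def pathomics_score(model: PathomicsModel, X: pd.DataFrame) -> pd.Series:
    """Per-patient pathomics score: P(high-expression class), in [0, 1]."""
    X = pd.DataFrame(X)
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"unknown/missing features: {missing}")
    Xm = X[model.feature_names]
    tag = model.predictor[0]
    if tag == "linear":
        _, coefs, intercept = model.predictor
        eta = Xm.to_numpy(dtype=float) @ coefs.to_numpy() + intercept
        ps = 1.0 / (1.0 + np.exp(-eta))
    elif tag == "sklearn":
        clf = model.predictor[1]
        pos = int(np.flatnonzero(clf.classes_ == 1)[0])
        ps = clf.predict_proba(Xm.to_numpy())[:, pos]
    else:  # pragma: no cover
        raise ValueError(f"unknown predictor tag {tag!r}")
    return pd.Series(np.clip(ps, 0.0, 1.0), index=Xm.index, name="pathomics_score")


def wilcoxon_rank_sum(values_a, values_b) -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_a + n_b <= 12 and there are no ties, otherwise
    the tie-corrected normal approximation.  Returns (U statistic of group
    a, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size + b.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


class PathomicsClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end for the pathomics-score models.

    Parameters
    ----------
    kind : "svm" or "lr"
        SVM with Platt scaling, or logistic regression (optionally reduced
        by backward stepwise AIC).
    """

    def __init__(self, kind: str = "svm", C: float = DEFAULT_SVM_C,
                 kernel: str = "linear", stepwise: bool = True,
                 platt_folds: int = PLATT_FOLDS):
        self.kind = kind
        self.C = C
        self.kernel = kernel
        self.stepwise = stepwise
        self.platt_folds = platt_folds

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if self.kind == "svm":
            self.model_ = fit_svm(X, y, C=self.C, kernel=self.kernel,
                                  platt_folds=self.platt_folds)
        elif self.kind == "lr":
            full = fit_logistic(X, y)
            self.model_ = (backward_stepwise_aic(X, y, full)
                           if self.stepwise and not full.penalized_fallback
                           else full)
        else:
            raise ValueError("kind must be 'svm' or 'lr'")
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        ps = pathomics_score(self.model_, pd.DataFrame(X)).to_numpy()
        return np.column_stack([1 - ps, ps])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_table(self, X, cohort: str = "train") -> pd.DataFrame:
        """Pathomics scores as a tidy table (patient_id, PS, model, cohort)."""
        check_is_fitted(self, "model_")
        ps = pathomics_score(self.model_, pd.DataFrame(X))
        return pd.DataFrame({"pathomics_score": ps, "model": self.kind,
                             "cohort": cohort})
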