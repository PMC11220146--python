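"""Feature selection: mRMR mutual-information ranking followed by RFE.

mRMR (minimum-redundancy maximum-relevance) greedily ranks features by the
MID (difference) criterion: the first pick maximizes I(f; y), each later
pick maximizes I(f; y) minus the mean mutual information with the already
selected features.  Mutual information is the plug-in estimate on
discretized features (equal-frequency binning, 4 bins by default).

RFE (recursive feature elimination) then repeatedly fits a linear
soft-margin SVM on the remaining standardized features and drops the
feature with the smallest absolute weight until the target count remains.

All ties (in MI scores and in |w|) break lexicographically on feature name
so selection is deterministic and invariant to column order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_MRMR_KEEP = 20
DEFAULT_RFE_TARGET = 6
MI_BINS = 4


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete vectors.

    I(X; Y) = sum_xy p(x, y) ln[p(x, y) / (p(x) p(y))] over the joint
    empirical distribution; zero iff the empirical table factorizes.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def discretize_equal_frequency(values: np.ndarray, bins: int = MI_BINS) -> np.ndarray:
    """Equal-frequency binning of a continuous vector into <= ``bins`` codes."""
    v = np.asarray(values, dtype=np.float64)
    qs = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, v, side="right")


def _discretize_matrix(X: pd.DataFrame, bins: int) -> dict:
    return {c: discretize_equal_frequency(X[c].to_numpy(), bins) for c in X.columns}


def mrmr_rank(X: pd.DataFrame, y, m: int = DEFAULT_MRMR_KEEP,
              bins: int = MI_BINS, criterion: str = "mid") -> list:
    """Greedy mRMR ranking of the top ``m`` features.

    Returns an ordered list of (feature_name, score) where score is the
    criterion value at the step the feature was picked: relevance I(f; y)
    for the first pick, and for later picks either the MID difference
    I(f; y) - mean_s I(f; s) (default) or the MIQ quotient
    I(f; y) / mean_s I(f; s).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if m > X.shape[1]:
        raise ValueError(f"m={m} exceeds {X.shape[1]} available features")
    if criterion not in ("mid", "miq"):
        raise ValueError("criterion must be 'mid' or 'miq'")
    disc = _discretize_matrix(X, bins)
    names = sorted(X.columns)  # lexicographic order resolves all ties
    relevance = {c: mutual_information(disc[c], y) for c in names}
    pair_mi: dict = {}

    def pair(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information(disc[key[0]], disc[key[1]])
        return pair_mi[key]

    selected: list = []
    remaining = list(names)
    while len(selected) < m:
        best_name, best_score = None, -np.inf
        for c in remaining:
            if not selected:
                score = relevance[c]
            else:
                red = np.mean([pair(c, s) for s, _ in selected])
                if criterion == "mid":
                    score = relevance[c] - red
                else:
                    score = relevance[c] / max(red, 1e-12)
            if score > best_score:  # strict: earlier (lexic. smaller) name wins ties
                best_name, best_score = c, score
        selected.append((best_name, float(best_score)))
        remaining.remove(best_name)
    return selected


def rfe(X: pd.DataFrame, y, target: int = DEFAULT_RFE_TARGET, step: int = 1,
        C: float = 1.0) -> tuple:
    """Recursive feature elimination with a linear SVM.

    Repeatedly fits a linear soft-margin SVM (C fixed) on the remaining
    features and drops the ``step`` features with the smallest absolute
    weights, until ``target`` remain.  Features are assumed standardized.

    Returns (selected_names, elimination_order) with the dropped features
    in drop order.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("RFE needs both classes present")
    if target > X.shape[1]:
        raise ValueError(f"target={target} exceeds {X.shape[1]} features")
    remaining = list(X.columns)
    eliminated: list = []
    while len(remaining) > target:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[remaining].to_numpy(), y)
        w = np.abs(clf.coef_.ravel())
        n_drop = min(step, len(remaining) - target)
        # sort by (|w|, name): smallest weight first, lexicographic tie-break
        order = sorted(range(len(remaining)), key=lambda i: (w[i], remaining[i]))
        for i in sorted(order[:n_drop], reverse=True):
            eliminated.append(remaining[i])
            del remaining[i]
    logger.info("RFE eliminated %d features: %s", len(eliminated), eliminated)
    return remaining, eliminated


class MRMRSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`mrmr_rank`."""

    def __init__(self, m: int = DEFAULT_MRMR_KEEP, bins: int = MI_BINS,
                 criterion: str = "mid"):
        self.m = m
        self.bins = bins
        self.criterion = criterion

    def fit(self, X, y):
        ranked = mrmr_rank(pd.DataFrame(X), y, m=self.m, bins=self.bins,
                           criterion=self.criterion)
        self.ranking_ = ranked
        self.selected_features_ = [name for name, _ in ranked]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]


class RFESelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`rfe`."""

    def __init__(self, target: int = DEFAULT_RFE_TARGET, step: int = 1,
                 C: float = 1.0):
        self.target = target
        self.step = step
        self.C = C

    def fit(self, X, y):
        selected, eliminated = rfe(pd.DataFrame(X), y, target=self.target,
                                   step=self.step, C=self.C)
        self.selected_features_ = selected
        self.elimination_order_ = eliminated
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]
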