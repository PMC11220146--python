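"""Model validation statistics.

ROC/AUC with DeLong variance and tests, confusion-matrix metrics at a
Youden-optimal threshold, stratified k-fold cross-validation of the whole
modeling pipeline (standardization, selection and calibration refit inside
every training fold), Hosmer-Lemeshow calibration, the Brier score, and
decision-curve analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from pathoscore.models import PathomicsClassifier
from pathoscore.selection import MRMRSelector, RFESelector
from pathoscore.texture import ZScoreScaler

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    """Empirical ROC curve with DeLong uncertainty for the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    variance: float          # DeLong variance of the AUC
    ci: tuple                # 95% Wald CI

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    return y


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple:
    """DeLong structural components (placement values) via midranks.

    V10[i] is the fraction of negatives scored below positive i (ties 1/2);
    V01[j] the fraction of positives scored above negative j.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc(scores, labels) -> ROCResult:
    """Empirical ROC and trapezoidal AUC (= tie-corrected Mann-Whitney
    U / (n1 n0)) with DeLong variance and 95% CI."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    distinct = np.flatnonzero(np.diff(ss) != 0)
    idx = np.concatenate([distinct, [len(ss) - 1]])
    tps = np.cumsum(ys)[idx]
    fps = (idx + 1) - tps
    tpr = np.concatenate([[0], tps / tps[-1]])
    fpr = np.concatenate([[0], fps / fps[-1]])
    a = float(np.trapezoid(tpr, fpr))
    v10, v01 = _placements(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.96 * np.sqrt(var)
    return ROCResult(fpr, tpr, a, float(var), (a - half, a + half))


def delong_ci(scores, labels, level: float = 0.95) -> tuple:
    """DeLong confidence interval for one AUC."""
    r = auc(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2)
    return (r.auc - z * r.se, r.auc + z * r.se)


def delong_test(scores_1, scores_2, labels) -> tuple:
    """DeLong test for two correlated AUCs on the same cases.

    Returns (z, two-sided p).  Degenerate variance (e.g. both models
    perfectly separating) is reported as non-comparable.
    """
    y = _check_binary(labels)
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape or s1.shape[0] != y.shape[0]:
        raise ValueError("paired scores must cover identical cases")
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    a1, a2 = v10_1.mean(), v10_2.mean()
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if a1 == a2:
        return 0.0, 1.0
    if var <= 0:
        raise ValueError("degenerate DeLong variance: AUCs not comparable")
    z = (a1 - a2) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = SEN + SPE - 1, scanned over the
    midpoints of adjacent distinct scores."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    cands = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
    best_t, best_j = float(cands[0]), -np.inf
    for t in cands:
        pred = s >= t
        sen = pred[y == 1].mean()
        spe = (~pred[y == 0]).mean()
        j = sen + spe - 1
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def threshold_metrics(scores, labels, threshold: float | None = None) -> dict:
    """ACC/SEN/SPE/PPV/NPV at a threshold (Youden-optimal if omitted)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if threshold is None:
        threshold = youden_threshold(s, y)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    div = lambda a, b: a / b if b else np.nan
    return {
        "threshold": float(threshold),
        "ACC": div(tp + tn, tp + tn + fp + fn),
        "SEN": div(tp, tp + fn),
        "SPE": div(tn, tn + fp),
        "PPV": div(tp, tp + fp),
        "NPV": div(tn, tn + fn),
    }


def build_pipeline_steps(model_kind: str = "svm", mrmr_m: int | None = 20,
                         rfe_target: int | None = 6, C: float = 1.0,
                         stepwise: bool = True, platt_folds: int = 5) -> list:
    """The modeling steps refit inside every CV training fold."""
    steps = [ZScoreScaler()]
    if mrmr_m is not None:
        steps.append(MRMRSelector(m=mrmr_m))
    if rfe_target is not None:
        steps.append(RFESelector(target=rfe_target))
    steps.append(PathomicsClassifier(kind=model_kind, C=C, stepwise=stepwise,
                                     platt_folds=platt_folds))
    return steps


def _fit_score(steps, X_tr, y_tr, X_te):
    Xt, Xe = X_tr, X_te
    for step in steps[:-1]:
        step.fit(Xt, y_tr)
        Xt, Xe = step.transform(Xt), step.transform(Xe)
    clf = steps[-1]
    clf.fit(Xt, y_tr)
    return clf.predict_proba(Xe)[:, 1]


def kfold_cv(X: pd.DataFrame, y, k: int = 10, seed: int = 0,
             model_kind: str = "svm", mrmr_m: int | None = 20,
             rfe_target: int | None = 6, C: float = 1.0,
             stepwise: bool = True, platt_folds: int = 5) -> tuple:
    """Stratified k-fold cross-validation of the whole pipeline.

    Standardization, mRMR, RFE and probability calibration are refit inside
    each training fold; the pooled out-of-fold pathomics scores give one
    ROC.  ``k = n`` degenerates to leave-one-out (unstratified, seed-free).

    Returns (pooled out-of-fold scores as a Series on X's index, ROCResult).
    """
    X = pd.DataFrame(X)
    y = _check_binary(y)
    n = len(X)
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    if k == n:
        splitter = LeaveOneOut()
        splits = splitter.split(X)
    else:
        counts = np.bincount(y)
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} cases; cannot stratify into {k} folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    pooled = np.full(n, np.nan)
    for tr, te in splits:
        steps = build_pipeline_steps(model_kind, mrmr_m, rfe_target, C,
                                     stepwise, platt_folds)
        pooled[te] = _fit_score(steps, X.iloc[tr], y[tr], X.iloc[te])
    scores = pd.Series(pooled, index=X.index, name="cv_pathomics_score")
    return scores, auc(pooled, y)


def holdout_split(y, test_size: float = 0.4, seed: int = 0) -> tuple:
    """Stratified random train/test index split (alternative to k-fold CV)."""
    y = _check_binary(y)
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_te = int(round(test_size * len(idx)))
        te_idx.extend(idx[:n_te])
        tr_idx.extend(idx[n_te:])
    return np.sort(tr_idx), np.sort(te_idx)


def hosmer_lemeshow(probs, labels, g: int = 10) -> tuple:
    """Hosmer-Lemeshow goodness-of-fit test with deciles of risk.

    Cases are grouped into ``g`` equal-count groups of predicted
    probability (groups emptied by ties are merged with a neighbor and the
    degrees of freedom adjusted).  Returns (chi2, df, p) with df = g' - 2.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if g < 3:
        raise ValueError("need at least 3 groups")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)[1:-1]))
    group = np.searchsorted(edges, p, side="right")
    chi2 = 0.0
    n_groups = 0
    for gi in np.unique(group):
        sel = group == gi
        ng = sel.sum()
        o = y[sel].sum()
        e = p[sel].sum()
        denom = e * (1 - e / ng)
        if denom <= 0:
            # perfectly extreme group: contributes 0 when O == E, else inf
            chi2 += 0.0 if np.isclose(o, e) else np.inf
        else:
            chi2 += (o - e) ** 2 / denom
        n_groups += 1
    if n_groups < g:
        logger.info("Hosmer-Lemeshow: %d of %d groups after tie merging",
                    n_groups, g)
    df = max(n_groups - 2, 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def brier_score(probs, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=float)
    return float(np.mean((p - y) ** 2))


def decision_curve(probs, labels, grid=None) -> pd.DataFrame:
    """Decision-curve analysis.

    Net benefit NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t), calling a case
    positive when its score is >= p_t.  The treat-all policy labels every
    case positive; treat-none is identically zero.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in np.asarray(grid, dtype=float):
        pos = p >= pt
        tp = float(np.sum(pos & (y == 1)))
        fp = float(np.sum(pos & (y == 0)))
        odds = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit_model": tp / n - (fp / n) * odds,
            "net_benefit_all": prev - (1 - prev) * odds,
            "net_benefit_none": 0.0,
        })
    return pd.DataFrame(rows)
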