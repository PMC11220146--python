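"""ROC/AUC, DeLong, thresholds, CV, calibration, Brier, decision curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_classification_frame
from pathoscore.evaluation import (
    auc,
    brier_score,
    decision_curve,
    delong_test,
    holdout_split,
    hosmer_lemeshow,
    kfold_cv,
    threshold_metrics,
    youden_threshold,
)


def auc_pair_oracle(scores, labels):
    """Concordance count over all positive-negative pairs (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def placement_oracle(scores, labels):
    """DeLong structural components by explicit double loops."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = [np.mean([psi(x, y) for y in neg]) for x in pos]
    v01 = [np.mean([psi(x, y) for x in pos]) for y in neg]
    return np.array(v10), np.array(v01)


class TestAUC:
    def test_perfect_and_null(self, rng):
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        assert auc(y.astype(float), y).auc == 1.0
        r = auc(rng.normal(size=5000), rng.integers(0, 2, 5000))
        assert 0.45 < r.auc < 0.55

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels).auc == pytest.approx(
            auc_pair_oracle(scores, labels))


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_symmetry_in_model_order(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s1, s2 = rng.normal(size=60), rng.normal(size=60)
        z12, p12 = delong_test(s1, s2, y)
        z21, p21 = delong_test(s2, s1, y)
        assert z12 == pytest.approx(-z21) and p12 == pytest.approx(p21)

    def test_components_match_placement_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 21))
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            from pathoscore.evaluation import _placements

            v10, v01 = _placements(scores, labels)
            o10, o01 = placement_oracle(scores, labels)
            # our placements are sorted per group by rankdata; compare as sets
            assert np.allclose(np.sort(v10), np.sort(o10))
            assert np.allclose(np.sort(v01), np.sort(o01))
            assert np.mean(v10) == pytest.approx(auc_pair_oracle(scores, labels))


class TestThresholdMetrics:
    def test_perfect_scores(self):
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        m = threshold_metrics(y.astype(float), y, threshold=0.5)
        assert all(m[k] == 1 for k in ("ACC", "SEN", "SPE", "PPV", "NPV"))

    def test_known_confusion_table(self):
        # TP=29, FN=0, TN=32, FP=17
        scores = np.r_[np.ones(29), np.zeros(32), np.ones(17)]
        labels = np.r_[np.ones(29), np.zeros(49)].astype(int)
        m = threshold_metrics(scores, labels, threshold=0.5)
        assert m["SEN"] == pytest.approx(1.0)
        assert m["SPE"] == pytest.approx(32 / 49, abs=5e-4)

    def test_youden_equals_brute_scan(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        t = youden_threshold(scores, labels)
        uniq = np.unique(scores)
        cands = (uniq[:-1] + uniq[1:]) / 2
        js = [( (scores >= c)[labels == 1].mean()
               + (scores < c)[labels == 0].mean() - 1, c) for c in cands]
        best_j = max(j for j, _ in js)
        j_at_t = ((scores >= t)[labels == 1].mean()
                  + (scores < t)[labels == 0].mean() - 1)
        assert j_at_t == pytest.approx(best_j)


class TestKFoldCV:
    def test_leave_one_out_is_deterministic(self):
        X, y = make_classification_frame(12, 2, 1, 1.5, seed=2)
        s1, r1 = kfold_cv(X, y, k=12, mrmr_m=None, rfe_target=None,
                          model_kind="lr", stepwise=False)
        s2, r2 = kfold_cv(X, y, k=12, mrmr_m=None, rfe_target=None,
                          model_kind="lr", stepwise=False)
        assert np.allclose(s1, s2) and r1.auc == r2.auc

    def test_stratification_within_one_case(self):
        X, y = make_classification_frame(55, 2, 2, 1.0, seed=3)
        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(5, shuffle=True, random_state=0).split(X, y))
        global_prop = y.mean()
        for _, te in folds:
            assert abs(y[te].sum() - global_prop * len(te)) <= 1

    def test_null_features_give_chance_auc(self):
        aucs = []
        for seed in range(10):
            X, y = make_classification_frame(60, 0, 10, 0.0, seed=seed)
            _, roc = kfold_cv(X, y, k=5, seed=seed, mrmr_m=None,
                              rfe_target=None, model_kind="svm", platt_folds=3)
            aucs.append(roc.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_cv_auc_below_resubstitution(self):
        from pathoscore.models import PathomicsClassifier

        deltas = []
        for seed in range(5):
            X, y = make_classification_frame(60, 3, 12, 0.8, seed=100 + seed)
            _, roc = kfold_cv(X, y, k=5, seed=seed, mrmr_m=None,
                              rfe_target=None, platt_folds=3)
            clf = PathomicsClassifier(kind="svm", platt_folds=3).fit(X, y)
            train_auc = auc(clf.predict_proba(X)[:, 1], y).auc
            deltas.append(train_auc - roc.auc)
        assert np.mean(deltas) > 0

    def test_class_too_small_for_stratification(self):
        X, y = make_classification_frame(20, 1, 1, 1.0, seed=0)
        y = np.zeros(20, dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError, match="stratify"):
            kfold_cv(X, y, k=10)

    def test_holdout_split_is_stratified(self):
        y = np.r_[np.zeros(30), np.ones(20)].astype(int)
        tr, te = holdout_split(y, test_size=0.4, seed=1)
        assert len(np.intersect1d(tr, te)) == 0
        assert y[te].sum() == 8 and len(te) == 20


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups(self):
        # probs equal to each group's event frequency
        probs = np.r_[np.full(40, 0.2), np.full(40, 0.5), np.full(40, 0.8)]
        labels = np.r_[np.r_[np.ones(8), np.zeros(32)],
                       np.r_[np.ones(20), np.zeros(20)],
                       np.r_[np.ones(32), np.zeros(8)]].astype(int)
        chi2, df, p = hosmer_lemeshow(probs, labels, g=3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_built_three_group_table(self):
        probs = np.r_[np.full(10, 0.1), np.full(10, 0.4), np.full(10, 0.7)]
        labels = np.r_[np.r_[np.ones(2), np.zeros(8)],
                       np.r_[np.ones(3), np.zeros(7)],
                       np.r_[np.ones(9), np.zeros(1)]].astype(int)
        chi2, df, p = hosmer_lemeshow(probs, labels, g=3)
        expected = sum((o - e) ** 2 / (e * (1 - e / 10))
                       for o, e in [(2, 1.0), (3, 4.0), (9, 7.0)])
        assert chi2 == pytest.approx(expected)
        assert df == 1


class TestBrier:
    def test_extremes(self):
        y = np.array([0, 1, 1, 0])
        assert brier_score(y.astype(float), y) == 0.0
        assert brier_score(np.full(4, 0.5), y) == 0.25

    def test_murphy_decomposition(self):
        probs = np.r_[np.full(20, 0.25), np.full(30, 0.75)]
        labels = np.r_[np.r_[np.ones(4), np.zeros(16)],
                       np.r_[np.ones(24), np.zeros(6)]].astype(int)
        bs = brier_score(probs, labels)
        ybar = labels.mean()
        rel = res = 0.0
        for p in (0.25, 0.75):
            sel = probs == p
            ok = labels[sel].mean()
            rel += sel.mean() * (p - ok) ** 2
            res += sel.mean() * (ok - ybar) ** 2
        unc = ybar * (1 - ybar)
        assert bs == pytest.approx(rel - res + unc)


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.r_[np.ones(20), np.zeros(30)].astype(int)
        nb = decision_curve(y.astype(float), y)
        assert np.allclose(nb["net_benefit_model"], 0.4)
        assert np.allclose(nb["net_benefit_none"], 0.0)

    def test_treat_all_hand_value(self):
        y = np.r_[np.ones(20), np.zeros(30)].astype(int)
        nb = decision_curve(np.full(50, 0.99), y, grid=[0.5])
        assert nb["net_benefit_all"].iloc[0] == pytest.approx(0.4 - 0.6)

    def test_matches_confusion_table_oracle(self, rng):
        probs = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        nb = decision_curve(probs, labels)
        n = len(labels)
        for _, row in nb.sample(10, random_state=0).iterrows():
            pt = row["threshold"]
            pred = probs >= pt
            tp = np.sum(pred & (labels == 1))
            fp = np.sum(pred & (labels == 0))
            assert row["net_benefit_model"] == pytest.approx(
                tp / n - fp / n * pt / (1 - pt))
        assert (nb["net_benefit_model"] <= labels.mean() + 1e-12).all()
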