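import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirage.classification import (
    binarize_age,
    classify_via_regression,
    confusion,
    fit_pls_logistic,
    linear_predictor,
    optimal_threshold,
    resampling_classify,
    roc_auc,
    select_K_auc,
    transfer_classify,
)
from nirage.model_selection import ValidationCurve, make_splits
from nirage.spectra_io import SampleTable


def concordance_auc(eta, is_old):
    """Brute-force Mann-Whitney AUC with ties counted 1/2 (oracle)."""
    eta = np.asarray(eta, float)
    is_old = np.asarray(is_old, bool)
    pos, neg = eta[is_old], eta[~is_old]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestBinarize:
    def make_meta(self, ages):
        return SampleTable(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(len(ages))],
                    "age_days": ages,
                    "cohort": ["lab"] * len(ages),
                    "group": ["g"] * len(ages),
                }
            )
        )

    def test_boundary_is_old(self):
        labels = binarize_age(self.make_meta([8.0, 7.99]))
        assert labels[0].is_old and labels[0].label == "old"
        assert not labels[1].is_old and labels[1].label == "young"

    def test_lab_design_split(self):
        labels = binarize_age(self.make_meta([2, 5, 8, 12, 15]))
        assert [lab.is_old for lab in labels] == [False, False, True, True, True]


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 10, 11], [False, False, True, True])
        assert r.auc == pytest.approx(1.0)

    def test_small_example(self):
        # 4 pairs: (0.35>0.1)=1, (0.35<0.4)=0, (0.8>0.1)=1, (0.8>0.4)=1
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        r = roc_auc([1.0, 1.0, 1.0, 1.0], [False, True, False, True])
        assert r.auc == pytest.approx(0.5)

    def test_curve_endpoints_monotone(self, rng):
        eta = rng.normal(size=50)
        is_old = rng.random(50) < 0.5
        is_old[0], is_old[1] = True, False
        r = roc_auc(eta, is_old)
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    @settings(derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 30))
    def test_trapezoid_equals_concordance(self, seed, n):
        rng = np.random.default_rng(seed)
        eta = np.round(rng.normal(size=n), 1)  # rounding forces ties
        is_old = rng.random(n) < 0.5
        if is_old.all() or not is_old.any():
            is_old[0] = ~is_old[0]
        r = roc_auc(eta, is_old)
        assert r.auc == pytest.approx(concordance_auc(eta, is_old), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        eta = rng.normal(size=40)
        is_old = rng.random(40) < 0.4
        is_old[:2] = [True, False]
        a = roc_auc(eta, is_old).auc
        b = roc_auc(np.exp(2 * eta), is_old).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestOptimalThreshold:
    def test_separable_midpoint(self):
        tau = optimal_threshold([-2, -1, 1, 2], [False, False, True, True])
        assert tau == pytest.approx(0.0)

    def test_overlapping_matches_exhaustive_oracle(self):
        eta = np.array([0.0, 2.0, 1.0, 3.0])
        labels = np.array([False, False, True, True])
        tau = optimal_threshold(eta, labels)
        err = np.sum((eta >= tau) != labels)
        best = min(
            np.sum((eta >= c) != labels)
            for c in np.concatenate([[-np.inf], np.unique(eta) - 1e-9, [np.inf]])
        )
        assert err == best == 1

    def test_never_beaten_by_any_cutpoint(self, rng):
        for _ in range(20):
            eta = rng.normal(size=12)
            labels = rng.random(12) < 0.5
            if labels.all() or not labels.any():
                continue
            tau = optimal_threshold(eta, labels)
            err = np.sum((eta >= tau) != labels)
            for c in np.concatenate([[-np.inf], eta - 1e-9, eta + 1e-9, [np.inf]]):
                assert err <= np.sum((eta >= c) != labels)

    def test_degenerate_equal_eta_majority_class(self):
        tau = optimal_threshold([1.0, 1.0, 1.0], [True, True, False])
        assert np.all(np.array([1.0, 1.0, 1.0]) >= tau)  # all called old


class TestConfusion:
    def test_counts_and_rates(self):
        # eta >= tau called old: tp=3, fn=1 -> sensitivity 0.75
        eta = [1, 2, 3, -1, -2, -3, -4, 5]
        labels = [True, True, True, True, False, False, False, False]
        c = confusion(eta, 0.0, labels)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 3)
        assert c.tpr == pytest.approx(0.75)
        assert c.tpr + c.fnr == pytest.approx(1.0)
        assert c.tnr + c.fpr == pytest.approx(1.0)

    def test_perfect_split_accuracy_one(self):
        c = confusion([-1, -2, 3, 4], 0.0, [False, False, True, True])
        assert c.accuracy == 1.0


class TestSelectKAUC:
    def test_example(self):
        curve = ValidationCurve(
            np.arange(1, 5), [0.80, 0.87, 0.875, 0.88], metric_name="auc"
        )
        assert select_K_auc(curve, 0.01) == 2

    def test_flat(self):
        curve = ValidationCurve(np.arange(1, 4), [0.9, 0.9, 0.9], metric_name="auc")
        assert select_K_auc(curve) == 1

    def test_zero_tol_argmax(self):
        curve = ValidationCurve(
            np.arange(1, 5), [0.7, 0.9, 0.9, 0.8], metric_name="auc"
        )
        assert select_K_auc(curve, 0.0) == 2


class TestPLSLogistic:
    def test_separable_training_auc_one(self, rng):
        n = 30
        labels = np.arange(n) < 15
        X = rng.normal(size=(n, 10))
        X[:, 0] += np.where(labels, 5.0, -5.0)
        m = fit_pls_logistic(X, labels, 2)
        eta = linear_predictor(m, X)
        assert roc_auc(eta, labels).auc == pytest.approx(1.0)

    def test_null_labels_training_auc_near_half(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 15))
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        m = fit_pls_logistic(X, labels, 2)
        # evaluate on fresh null data so training optimism cannot inflate it
        X_new = rng.normal(size=(60, 15))
        labels_new = rng.random(60) < 0.5
        labels_new[:2] = [True, False]
        auc = roc_auc(linear_predictor(m, X_new), labels_new).auc
        assert 0.35 <= auc <= 0.65

    def test_K1_matches_direct_univariate_logistic(self, rng):
        """K=1 reduces to a 1-D logistic fit on the first PLS score; compare
        against an independent Newton solver."""
        n = 40
        labels = rng.random(n) < 0.5
        labels[:2] = [True, False]
        X = rng.normal(size=(n, 6)) + 0.8 * labels[:, None]
        m = fit_pls_logistic(X, labels, 1)
        t = m.pls.scores(X)[:, 0]

        # independent 1-D IRLS oracle
        beta = np.zeros(2)
        D = np.column_stack([np.ones(n), t])
        for _ in range(100):
            p = 1 / (1 + np.exp(-(D @ beta)))
            W = p * (1 - p)
            grad = D.T @ (labels - p)
            H = D.T @ (D * W[:, None])
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert m.alpha == pytest.approx(beta[0], abs=1e-6)
        assert m.beta[0] == pytest.approx(beta[1], abs=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_pls_logistic(rng.normal(size=(10, 4)), [True] * 10, 1)


class TestResamplingClassify:
    def test_strong_signal_high_auc(self, lab_subset):
        spectra, y, groups = lab_subset
        is_old = y >= 8
        plan = make_splits(len(y), R=15, seed=3, strata=groups)
        cls = resampling_classify(spectra.values, is_old, plan, 8)
        assert cls.roc.auc >= 0.95
        assert cls.roc.per_randomisation_aucs.shape == (15,)
        assert set(cls.roc.auc_percentiles) >= {5, 25, 50, 75, 95}

    def test_shuffled_labels_null_auc(self, lab_subset):
        spectra, y, groups = lab_subset
        rng = np.random.default_rng(9)
        shuffled = rng.permutation(y >= 8)
        plan = make_splits(len(y), R=15, seed=4, strata=groups)
        cls = resampling_classify(spectra.values, shuffled, plan, 5)
        assert 0.4 <= cls.roc.auc <= 0.6

    def test_reproducible_under_seed(self, lab_subset):
        spectra, y, groups = lab_subset
        is_old = y >= 8
        plan = make_splits(len(y), R=5, seed=6, strata=groups)
        a = resampling_classify(spectra.values, is_old, plan, 4)
        b = resampling_classify(spectra.values, is_old, plan, 4)
        assert a.selected_K == b.selected_K
        np.testing.assert_array_equal(
            a.eta["eta_mean"].to_numpy(), b.eta["eta_mean"].to_numpy()
        )

    def test_identical_taus_average_to_same(self):
        from nirage.classification import _finite_mean

        assert _finite_mean(np.array([1.3, 1.3, 1.3])) == pytest.approx(1.3)

    def test_transfer_classification_degrades(self, lab_subset, field_subset):
        lab_s, lab_y, lab_g = lab_subset
        field_s, field_y, _ = field_subset
        plan = make_splits(len(lab_y), R=15, seed=5, strata=lab_g)
        cls = resampling_classify(lab_s.values, lab_y >= 8, plan, 8)
        conf, roc, df = transfer_classify(cls, field_s.values, field_y >= 8)
        assert roc.auc <= cls.roc.auc - 0.1
        assert len(df) == len(field_y)


class TestClassifyViaRegression:
    def preds(self, y_true, y_hat):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(y_true))],
                "y_true": y_true,
                "y_hat": y_hat,
            }
        )

    def test_correct_calls(self):
        c = classify_via_regression(self.preds([2, 15], [2.1, 14.7]))
        assert c.accuracy == 1.0

    def test_boundary_prediction_is_old(self):
        c = classify_via_regression(self.preds([2, 15], [8.0, 8.0]))
        assert c.tp + c.fp == 2  # everything called old

    def test_agrees_with_composition(self, rng):
        y_true = rng.uniform(0, 16, size=30)
        y_hat = y_true + rng.normal(scale=2.0, size=30)
        c = classify_via_regression(self.preds(y_true, y_hat))
        manual_old = y_hat >= 8
        true_old = y_true >= 8
        assert c.tp == np.sum(manual_old & true_old)
        assert c.tn == np.sum(~manual_old & ~true_old)
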