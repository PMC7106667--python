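import numpy as np
import pytest

from nirage.model_selection import (
    SplitPlan,
    ValidationCurve,
    loocv_curve,
    make_splits,
    resampling_fit_predict,
    resampling_validation,
    select_K_resampling,
    select_K_standard,
    transfer_evaluate,
)
from nirage.pls_core import fit_pls, predict_age, rmsd
from nirage.preprocess import PreprocessSpec, apply_preprocess
from nirage.spectra_io import SpectraSet


def linear_problem(n=40, p=20, noise=0.0, seed=0):
    """Spectra-like X whose first direction carries y exactly."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(1, 15, size=n)
    signal = np.linspace(0, 1, p)
    X = np.outer(y, signal) + noise * rng.normal(size=(n, p))
    return X, y


class TestMakeSplits:
    def test_partition_and_sizes_n100(self):
        plan = make_splits(100, R=20, seed=0)
        for tr, va, te in plan.splits:
            assert len(tr) == 50 and len(va) == 25 and len(te) == 25
            assert len(np.unique(np.concatenate([tr, va, te]))) == 100

    def test_same_seed_identical(self):
        a = make_splits(37, R=5, seed=42)
        b = make_splits(37, R=5, seed=42)
        for (t1, v1, e1), (t2, v2, e2) in zip(a.splits, b.splits):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2)
            assert np.array_equal(e1, e2)

    def test_test_appearance_counts(self):
        # each of 12 samples should land in test about R/4 times
        plan = make_splits(12, R=100, seed=1)
        counts = np.zeros(12)
        for _, _, te in plan.splits:
            counts[te] += 1
        assert np.all(np.abs(counts - 25) <= 15)

    def test_stratified_all_groups_everywhere(self):
        strata = np.repeat(["a", "b", "c"], 8)
        plan = make_splits(24, R=10, seed=2, strata=strata)
        for tr, va, te in plan.splits:
            for part in (tr, va, te):
                assert set(strata[part]) == {"a", "b", "c"}

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            make_splits(10, R=2, seed=0, strata=["tiny"] * 3 + ["big"] * 7)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            SplitPlan(
                n=4,
                R=1,
                splits=[(np.array([0, 1]), np.array([1]), np.array([3]))],
                seed=0,
                stratified=False,
            )


class TestLOOCV:
    def test_noiseless_single_column_perfect(self):
        # a perfect one-column signal survives every deletion
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 15, size=15)
        X = (y - y.mean())[:, None]
        curve = loocv_curve(X, y, 1)
        assert curve.metric_per_K[0] < 1e-8

    def test_small_noise_small_error(self):
        X, y = linear_problem(n=15, p=8, noise=0.01)
        curve = loocv_curve(X, y, 3)
        assert curve.metric_per_K.min() < 0.1

    def test_curve_shape(self):
        X, y = linear_problem(n=5, p=6, noise=0.1)
        assert loocv_curve(X, y, 3).K_grid.tolist() == [1, 2, 3]

    def test_pure_noise_no_better_than_mean_baseline(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        curve = loocv_curve(X, y, 4)
        baseline = np.std(y)
        assert curve.metric_per_K.min() >= baseline * 0.75

    def test_infeasible_kmax(self):
        X, y = linear_problem(n=5, p=6)
        with pytest.raises(ValueError, match="Kmax"):
            loocv_curve(X, y, 4)


class TestSelectionRules:
    def test_standard_rule_example(self):
        curve = ValidationCurve(np.arange(1, 6), [3.0, 2.5, 2.1, 2.0, 2.05])
        assert select_K_standard(curve, rel_tol=0.02) == 4

    def test_standard_flat_curve(self):
        curve = ValidationCurve(np.arange(1, 4), [2.0, 2.0, 2.0])
        assert select_K_standard(curve) == 1

    def test_standard_zero_tol_is_argmin(self):
        curve = ValidationCurve(np.arange(1, 5), [3.0, 1.0, 1.0, 2.0])
        assert select_K_standard(curve, rel_tol=0.0) == 2

    def test_resampling_rule_example(self):
        curve = ValidationCurve(np.arange(1, 6), [3.0, 2.5, 2.1, 2.0, 2.05])
        assert select_K_resampling(curve, tol_days=0.5) == 2

    def test_resampling_flat_curve(self):
        curve = ValidationCurve(np.arange(1, 4), [1.0, 1.0, 1.0])
        assert select_K_resampling(curve) == 1

    def test_resampling_zero_tol_is_argmin(self):
        curve = ValidationCurve(np.arange(1, 5), [3.0, 1.0, 1.0, 2.0])
        assert select_K_resampling(curve, tol_days=0.0) == 2

    def test_resampling_never_exceeds_argmin(self, rng):
        for _ in range(20):
            vals = rng.uniform(1, 5, size=8)
            curve = ValidationCurve(np.arange(1, 9), vals)
            assert select_K_resampling(curve, 0.5) <= int(np.argmin(vals)) + 1


class TestResamplingValidation:
    def test_noiseless_signal_near_zero(self):
        X, y = linear_problem(n=24, p=10)
        plan = make_splits(24, R=5, seed=0)
        curve = resampling_validation(X, y, plan, 1)
        assert np.all(curve.metric_per_K < 1e-8)

    def test_matrix_shape_and_consistency(self):
        X, y = linear_problem(n=24, p=10, noise=0.3)
        plan = make_splits(24, R=7, seed=1)
        curve = resampling_validation(X, y, plan, 4)
        assert curve.per_randomisation_metric.shape == (7, 4)
        np.testing.assert_allclose(
            curve.per_randomisation_metric.mean(axis=0), curve.metric_per_K
        )


class TestResamplingFitPredict:
    def test_noiseless_signal_recovered(self):
        X, y = linear_problem(n=24, p=10)
        plan = make_splits(24, R=10, seed=0)
        res = resampling_fit_predict(X, y, plan, 1)
        assert res.rmsd < 1e-8
        # all per-randomisation coefficient functions agree in this limit
        assert np.max(np.abs(res.coefs - res.coef_mean[None, :])) < 1e-6

    def test_every_sample_appears_in_test(self):
        plan = make_splits(40, R=100, seed=5)
        counts = np.zeros(40)
        for _, _, te in plan.splits:
            counts[te] += 1
        assert np.all(counts >= 1)

    def test_degenerate_plan_reproduces_training_fit(self):
        X, y = linear_problem(n=12, p=6, noise=0.2, seed=2)
        idx = np.arange(12)
        plan = SplitPlan(
            n=12,
            R=1,
            splits=[(idx, np.array([], dtype=int), idx)],
            seed=0,
            stratified=False,
        )
        res = resampling_fit_predict(X, y, plan, 2)
        direct = predict_age(fit_pls(X, y, 2), X)
        np.testing.assert_allclose(res.predictions["y_hat"].to_numpy(), direct)

    def test_shuffled_response_matches_mean_baseline(self, lab_subset):
        spectra, y, groups = lab_subset
        rng = np.random.default_rng(7)
        ysh = rng.permutation(y)
        plan = make_splits(len(y), R=15, seed=8, strata=groups)
        curve = resampling_validation(spectra.values, ysh, plan, 8)
        K = select_K_resampling(curve)
        res = resampling_fit_predict(spectra.values, ysh, plan, K)
        baseline = rmsd(ysh, np.full_like(ysh, ysh.mean()))
        assert abs(res.rmsd - baseline) <= 0.10 * baseline


class TestTransferEvaluate:
    def test_identity_transfer_reproduces_predictions(self):
        X, y = linear_problem(n=20, p=8, noise=0.1, seed=4)
        model = fit_pls(X, y, 2)
        t_rmsd, summary, preds = transfer_evaluate(
            model, X, y, ["g"] * 20
        )
        assert t_rmsd == pytest.approx(rmsd(y, predict_age(model, X)))
        assert summary.loc[0, "n"] == 20

    def test_snv_makes_baseline_offset_harmless(self):
        # SNV removes per-spectrum affine distortion, so an offset cohort
        # shift cannot move the predictions
        X, y = linear_problem(n=20, p=30, noise=0.05, seed=5)
        wl = 700 + 3.0 * np.arange(30)
        ids = [f"s{i}" for i in range(20)]
        snv_spec = PreprocessSpec(method="snv")

        def prep(M):
            s = SpectraSet(wl, M + 2.0, "absorbance", ids)  # keep rows non-constant
            return apply_preprocess(s, snv_spec).values

        Xp = prep(X)
        model = fit_pls(Xp, y, 2)
        r0, _, _ = transfer_evaluate(model, Xp, y, ["g"] * 20)
        r1, _, _ = transfer_evaluate(model, prep(X + 0.5), y, ["g"] * 20)
        assert r1 == pytest.approx(r0, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        X, y = linear_problem(n=10, p=8)
        model = fit_pls(X, y, 1)
        with pytest.raises(ValueError, match="re-trim"):
            transfer_evaluate(model, np.ones((5, 7)), np.ones(5), ["g"] * 5)

    def test_cohort_shift_degrades_transfer(self, lab_subset, field_subset):
        lab_s, lab_y, lab_g = lab_subset
        field_s, field_y, field_g = field_subset
        plan = make_splits(len(lab_y), R=15, seed=3, strata=lab_g)
        res = resampling_fit_predict(lab_s.values, lab_y, plan, 2)
        t_rmsd, _, _ = transfer_evaluate(
            res, field_s.values, field_y, field_g
        )
        assert t_rmsd > 1.5 * res.rmsd
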