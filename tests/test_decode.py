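import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from prefdecode.decode import (DEFAULT_LAMBDA_GRID, L1LogisticRegression,
                               PatternDecoder, extract_features,
                               fit_l1_logistic, kfold_predict, loso_predict,
                               permutation_test, select_lambda_nested,
                               univariate_baseline)


def _logit_data(rng, n=60, p=8, informative=2, slope=1.5, noise=0.3):
    X = rng.normal(size=(n, p))
    eta = X[:, :informative].sum(axis=1) * slope + rng.normal(0, noise, n)
    y = 1.0 / (1.0 + np.exp(-eta))
    return X, y


class TestGridDefault:
    def test_paper_grid_values(self):
        # 12 values, 2^-8 down to 2^-13.5 in half-log2 steps
        assert len(DEFAULT_LAMBDA_GRID) == 12
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(2.0 ** -8)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(2.0 ** -13.5)
        assert np.all(np.diff(DEFAULT_LAMBDA_GRID) < 0)


class TestL1Fit:
    def test_full_shrinkage_gives_logit_mean(self, rng):
        X, y = _logit_data(np.random.default_rng(0))
        coef, b0 = fit_l1_logistic(X, y, lam=10.0)
        assert np.all(coef == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                   abs=1e-4)

    def test_unpenalized_matches_newton_oracle(self):
        # independent Newton-Raphson MLE of the fractional-response logit
        rng = np.random.default_rng(1)
        X, y = _logit_data(rng, n=200, p=4)
        m = L1LogisticRegression(lam=0.0, tol=1e-10, max_outer=200,
                                 max_inner=500).fit(X, y)
        Xd = np.column_stack([np.ones(len(y)), X])
        th = np.zeros(5)
        for _ in range(100):
            p_hat = 1 / (1 + np.exp(-Xd @ th))
            W = p_hat * (1 - p_hat)
            grad = Xd.T @ (y - p_hat)
            H = (Xd * W[:, None]).T @ Xd
            step = np.linalg.solve(H, grad)
            th += step
            if np.abs(step).max() < 1e-12:
                break
        assert m.intercept_ == pytest.approx(th[0], abs=1e-5)
        assert np.allclose(m.coef_, th[1:], atol=1e-5)

    def test_unpenalized_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X, y = _logit_data(rng, n=150, p=3)
        m = L1LogisticRegression(lam=0.0, tol=1e-10, max_outer=200,
                                 max_inner=500).fit(X, y)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.GLM(y, sm.add_constant(X),
                         family=sm.families.Binomial()).fit()
        assert m.intercept_ == pytest.approx(ref.params[0], abs=1e-5)
        assert np.allclose(m.coef_, ref.params[1:], atol=1e-5)

    def test_planted_feature_recovered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            X = rng.normal(size=(200, 50))
            eta = 2.0 * X[:, 7]
            y = 1 / (1 + np.exp(-(eta + rng.normal(0, 0.3, 200))))
            coef, _ = fit_l1_logistic(X, y, lam=DEFAULT_LAMBDA_GRID[6])
            if coef[7] > 0:
                hits += 1
        assert hits >= 19

    def test_regularization_path_monotone_sparsity(self, rng):
        X, y = _logit_data(np.random.default_rng(3), n=40, p=30)
        # count nonzeros on a wide grid including strong penalties
        grid = 2.0 ** -np.arange(2.0, 10.0, 1.0)
        nnz = [np.count_nonzero(fit_l1_logistic(X, y, lam)[0])
               for lam in grid]
        assert all(a <= b + 1 for a, b in zip(nnz, nnz[1:]))  # near-monotone
        assert nnz[0] <= nnz[-1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_l1_logistic(np.array([[np.inf]]), np.array([0.5]), 0.1)
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            fit_l1_logistic(np.zeros((3, 2)), np.array([0.2, 1.4, 0.5]), 0.1)


class TestLambdaSelection:
    def test_grid_of_length_one(self, rng):
        X, y = _logit_data(np.random.default_rng(4), n=10)
        assert select_lambda_nested(X, y, np.array([0.01])) == 0.01

    def test_pure_noise_selects_large_lambda(self):
        hits = 0
        for s in range(15):
            rng = np.random.default_rng(400 + s)
            X = rng.normal(size=(20, 30))
            y = rng.uniform(0.1, 0.9, 20)
            lam = select_lambda_nested(X, y)
            if lam >= DEFAULT_LAMBDA_GRID[3]:  # among the 4 largest of 12
                hits += 1
        assert hits >= 12  # >= 80 %

    def test_strong_signal_selects_smaller_lambda(self):
        # on a grid wide enough that its upper half truly shrinks the
        # model, a strong low-noise signal pushes the selection into the
        # weak-penalty half
        grid = 2.0 ** -np.arange(1.0, 13.0, 1.0)
        lams = []
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            X, y = _logit_data(rng, n=50, p=10, slope=2.0, noise=0.1)
            lams.append(select_lambda_nested(X, y, grid))
        assert np.median(lams) < np.median(grid)


class TestLoso:
    def test_no_leakage_from_leftout_outcome(self):
        # altering the held-out subject's outcome must not move its
        # prediction
        rng = np.random.default_rng(5)
        X, y = _logit_data(rng, n=12, p=6)
        res1 = loso_predict(X, y)
        y2 = y.copy()
        y2[4] = np.clip(1.0 - y2[4], 0.01, 0.99)
        res2 = loso_predict(X, y2)
        assert res1.y_pred[4] == pytest.approx(res2.y_pred[4], abs=1e-12)

    def test_predictions_in_unit_interval(self):
        rng = np.random.default_rng(6)
        X, y = _logit_data(rng, n=10, p=5)
        res = loso_predict(X, y)
        assert np.all((res.y_pred > 0) & (res.y_pred < 1))
        assert len(res.chosen_lambda) == 10

    def test_null_mean_r_near_zero(self):
        rs = []
        for s in range(30):
            rng = np.random.default_rng(600 + s)
            X = rng.normal(size=(12, 8))
            y = rng.uniform(0.2, 0.8, 12)
            rs.append(loso_predict(X, y).r)
        assert abs(np.nanmean(rs)) < 2.0 / np.sqrt(12)

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="constant outcome"):
            loso_predict(rng.normal(size=(6, 3)), np.full(6, 0.5))

    def test_scale_equivariance_with_standardization(self):
        rng = np.random.default_rng(8)
        X, y = _logit_data(rng, n=10, p=4)
        r1 = loso_predict(X, y)
        r2 = loso_predict(X * 37.5, y)
        assert np.allclose(r1.y_pred, r2.y_pred, atol=1e-10)


class TestKfold:
    def test_k_equals_n_matches_loso(self):
        rng = np.random.default_rng(9)
        X, y = _logit_data(rng, n=8, p=4)
        a = loso_predict(X, y)
        b = kfold_predict(X, y, k=8)
        assert np.allclose(a.y_pred, b.y_pred)

    def test_k2_on_n4_runs(self):
        rng = np.random.default_rng(10)
        X, y = _logit_data(rng, n=4, p=3)
        res = kfold_predict(X, y, k=2, lambda_grid=np.array([0.01]))
        assert len(res.y_pred) == 4

    def test_different_seeds_differ_but_agree_roughly(self):
        rng = np.random.default_rng(11)
        X, y = _logit_data(rng, n=30, p=5, slope=2.0, noise=0.2)
        r1 = kfold_predict(X, y, k=5, seed=1).r
        r2 = kfold_predict(X, y, k=5, seed=2).r
        assert r1 != r2
        assert abs(r1 - r2) < 0.5

    def test_k_validation(self):
        rng = np.random.default_rng(12)
        X, y = _logit_data(rng, n=6, p=3)
        with pytest.raises(ValueError, match="k must be"):
            kfold_predict(X, y, k=1)


class TestPermutation:
    def test_exhaustive_identity_only(self):
        # generic values, y_pred == y_obs: of the 120 permutations of
        # n = 5 only the identity reaches r = 1, so p = 1/120
        y = np.array([0.11, 0.27, 0.52, 0.68, 0.90])
        res = permutation_test(y, y, exact=True)
        assert res.n_perm == 120
        assert res.p == pytest.approx(1.0 / 120)

    def test_sampled_matches_exhaustive(self):
        rng = np.random.default_rng(13)
        y_obs = rng.uniform(0, 1, 5)
        y_pred = rng.uniform(0, 1, 5)
        exact = permutation_test(y_obs, y_pred, exact=True)
        sampled = permutation_test(y_obs, y_pred, n_perm=100_000, seed=3)
        assert sampled.p == pytest.approx(exact.p, abs=0.01)

    def test_below_median_observed_gives_large_p(self):
        # anti-correlated prediction: most permutations beat it
        y_obs = np.linspace(0.1, 0.9, 10)
        y_pred = y_obs[::-1].copy()
        res = permutation_test(y_obs, y_pred, n_perm=2000, seed=0)
        assert res.p > 0.5

    def test_zero_count_reported_as_bound(self):
        y_obs = np.linspace(0.05, 0.95, 30)
        res = permutation_test(y_obs, y_obs, n_perm=1000, seed=1)
        assert res.null_exceed_count == 0 and res.p == 0.0
        assert res.p_str.startswith("<")
        assert res.p_plus_one == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(0, 1, 20)
        r1 = permutation_test(a, b, n_perm=5000, seed=42)
        r2 = permutation_test(a, b, n_perm=5000, seed=42)
        assert r1.p == r2.p and r1.null_exceed_count == r2.null_exceed_count

    def test_validation(self):
        y = np.linspace(0.1, 0.9, 5)
        with pytest.raises(ValueError, match="constant"):
            permutation_test(np.full(5, 0.3), y)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(y, y[::-1].copy(), n_perm=10)


class TestFeaturesAndBaseline:
    def test_feature_matrix_shape_and_order(self, rng):
        mask = np.zeros((6, 6, 6), bool)
        mask[1, 1, 1] = mask[2, 3, 4] = mask[5, 5, 5] = True
        maps = np.arange(10 * 216, dtype=float).reshape(10, 6, 6, 6)
        ids = [f"sub-{i:02d}" for i in range(10, 0, -1)]
        fm = extract_features(maps, mask, ids)
        assert fm.values.shape == (10, 3)
        assert fm.subject_ids == sorted(ids)
        # shuffling input order but keeping the id pairing is a no-op
        perm = np.random.default_rng(0).permutation(10)
        fm2 = extract_features(maps[perm], mask, [ids[i] for i in perm])
        assert np.array_equal(fm.values, fm2.values)

    def test_masked_out_voxels_never_enter(self, rng):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        maps = rng.normal(size=(5, 4, 4, 4))
        fm = extract_features(maps, mask)
        assert fm.values.shape == (5, 1)
        assert np.array_equal(fm.values[:, 0], maps[:, 0, 0, 0])

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="different grids"):
            extract_features(rng.normal(size=(3, 4, 4, 4)),
                             np.ones((5, 5, 5), bool))

    def test_single_voxel_roi_mean_equals_value(self, rng):
        labels = np.zeros((4, 4, 4), int)
        labels[2, 2, 2] = 1
        maps = rng.normal(size=(8, 4, 4, 4))
        y = np.linspace(0.2, 0.8, 8)
        table = univariate_baseline(maps, labels, y, run_mvpa=False)
        r_ref = stats.pearsonr(maps[:, 2, 2, 2], y)[0]
        assert table.iloc[0]["r_mean_signal"] == pytest.approx(r_ref)

    def test_informative_roi_beats_noise_roi(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            labels = np.zeros((6, 6, 6), int)
            labels[:2] = 1
            labels[4:] = 2
            maps = rng.normal(size=(30, 6, 6, 6))
            signal = rng.normal(size=30)
            maps[:, labels == 1] += signal[:, None]
            y = 1 / (1 + np.exp(-(signal + rng.normal(0, 0.5, 30))))
            tab = univariate_baseline(maps, labels, y, run_mvpa=False)
            r1 = abs(tab[tab.roi == 1]["r_mean_signal"].iloc[0])
            r2 = abs(tab[tab.roi == 2]["r_mean_signal"].iloc[0])
            wins += r1 > r2
        assert wins >= 9


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        dec = PatternDecoder(cv=5, seed=3)
        params = dec.get_params()
        dec2 = PatternDecoder(**params)
        assert dec2.get_params() == params

    def test_fitted_attributes_and_predict(self):
        rng = np.random.default_rng(15)
        X, y = _logit_data(rng, n=12, p=5)
        dec = PatternDecoder().fit(X, y)
        for attr in ("y_pred_", "r_", "rmse_", "coef_", "intercept_",
                     "lambda_per_fold_"):
            assert hasattr(dec, attr)
        pred = dec.predict(X[:3])
        assert pred.shape == (3,) and np.all((pred > 0) & (pred < 1))
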