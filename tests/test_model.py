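"""Elastic-net model: residualization, solver oracles, CV tuning, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacni import (
    ElasticNetConfig,
    WeightsTable,
    fit_elastic_net,
    haufe_importance,
    residualize,
    score_subjects,
    tune_and_train,
)
from pacni.errors import ConfigError, DataError
from pacni.model import apply_residualization, fit_fold, make_folds


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self, rng):
        y = rng.normal(size=200)
        C = rng.normal(size=(200, 3))
        resid, _ = residualize(y, C)
        for j in range(3):
            assert abs(resid @ C[:, j]) <= 1e-8 * 200

    def test_hand_computed_normal_equations(self):
        # y = 2*sex + e on three points; solve X'X b = X'y by hand
        sex = np.array([0.0, 1.0, 1.0])
        y = np.array([0.1, 2.2, 1.9])
        X = np.column_stack([np.ones(3), sex])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        _, coef = residualize(y, sex)
        assert np.allclose(coef, expected, atol=1e-12)

    def test_orthogonal_target_unchanged(self):
        cov = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal, zero-mean
        resid, coef = residualize(y, cov)
        assert np.allclose(resid, y, atol=1e-12)
        assert abs(coef[1]) < 1e-12

    def test_rank_deficient_covariates_rejected(self, rng):
        C = rng.normal(size=(20, 2))
        C = np.column_stack([C, C[:, 0] * 2.0])
        with pytest.raises(DataError, match="rank"):
            residualize(rng.normal(size=20), C)

    def test_apply_uses_stored_coefficients_only(self, rng):
        y_tr, C_tr = rng.normal(size=50), rng.normal(size=(50, 2))
        _, coef = residualize(y_tr, C_tr)
        y_te, C_te = rng.normal(size=10), rng.normal(size=(10, 2))
        r1 = apply_residualization(y_te, C_te, coef)
        # permuting the new targets permutes residuals but cannot touch coef
        perm = rng.permutation(10)
        r2 = apply_residualization(y_te[perm], C_te[perm], coef)
        assert np.array_equal(r1[perm], r2)


class TestElasticNetOracles:
    def test_lambda_zero_matches_ols(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        wt = fit_elastic_net(X, y, alpha=0.5, lam=0.0)
        A = np.column_stack([np.ones(5), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(list(wt.weights.values()), coef[1:], atol=1e-6)
        assert abs(wt.intercept - coef[0]) < 1e-6

    def test_alpha_zero_matches_closed_form_ridge(self, rng):
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=60)
        lam = 0.3
        wt = fit_elastic_net(X, y, alpha=0.0, lam=lam)
        # independent oracle: ridge normal equations on standardized scale
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        yc = y - y.mean()
        beta_s = np.linalg.solve(
            Xs.T @ Xs / len(y) + lam * np.eye(4), Xs.T @ yc / len(y)
        )
        got = np.array(list(wt.weights.values())) * sd
        assert np.allclose(got, beta_s, atol=1e-6)

    def test_alpha_one_single_predictor_soft_threshold(self, rng):
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40) * 0.5
        lam = 0.1
        wt = fit_elastic_net(x[:, None], y, alpha=1.0, lam=lam)
        xs = (x - x.mean()) / x.std()
        rho = xs @ (y - y.mean()) / len(y)
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
        got = list(wt.weights.values())[0] * x.std()
        assert abs(got - expected) < 1e-8

    def test_large_lambda_full_shrinkage(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        wt = fit_elastic_net(X, y, alpha=1.0, lam=1e6)
        assert all(v == 0.0 for v in wt.weights.values())
        assert abs(wt.intercept - y.mean()) < 1e-10

    def test_l1_norm_nonincreasing_in_lambda(self, rng):
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        norms = []
        for lam in (0.01, 0.05, 0.1, 0.5, 1.0, 5.0):
            wt = fit_elastic_net(X, y, alpha=0.7, lam=lam)
            norms.append(sum(abs(v) for v in wt.weights.values()))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    @pytest.mark.parametrize("alpha,lam", [(-0.1, 1.0), (1.1, 1.0), (0.5, -1.0)])
    def test_invalid_grid_point_rejected(self, rng, alpha, lam):
        with pytest.raises(ConfigError):
            fit_elastic_net(rng.normal(size=(5, 2)), rng.normal(size=5), alpha, lam)

    def test_non_finite_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            fit_elastic_net(X, rng.normal(size=5), 0.5, 0.1)


class TestScoring:
    def test_arithmetic(self):
        wt = WeightsTable({"a": 2.0, "b": -1.0}, intercept=0.5)
        X = pd.DataFrame({"a": [1.0], "b": [2.0]})
        assert score_subjects(X, wt).iloc[0] == pytest.approx(0.5)

    def test_all_zero_weights_gives_intercept(self, rng):
        wt = WeightsTable({"a": 0.0, "b": 0.0}, intercept=3.25)
        X = pd.DataFrame(rng.normal(size=(7, 2)), columns=["a", "b"])
        assert np.allclose(score_subjects(X, wt), 3.25)

    def test_zero_weight_feature_may_be_absent(self, rng):
        wt = WeightsTable({"a": 1.0, "b": 0.0}, intercept=0.0)
        X = pd.DataFrame({"a": rng.normal(size=4)})
        assert np.allclose(score_subjects(X, wt), X["a"])

    def test_missing_nonzero_feature_is_error(self, rng):
        wt = WeightsTable({"a": 1.0, "b": 2.0}, intercept=0.0)
        X = pd.DataFrame({"a": rng.normal(size=4)})
        with pytest.raises(DataError, match="b"):
            score_subjects(X, wt)
        # explicit opt-in succeeds
        assert len(score_subjects(X, wt, allow_missing=True)) == 4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(-50, 50, allow_nan=False), j=st.integers(0, 2))
    def test_equivariance_constant_feature_shift(self, c, j):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        wt = WeightsTable({"a": 1.5, "b": -0.5, "c": 2.0}, intercept=1.0)
        base = score_subjects(X, wt)
        shifted = X.copy()
        col = X.columns[j]
        shifted[col] = shifted[col] + c
        delta = score_subjects(shifted, wt) - base
        assert np.allclose(delta, wt.weights[col] * c, atol=1e-9)


class TestTuneAndTrain:
    def _toy(self, n=40, p=6, seed=5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, p)),
            columns=[f"f{j}" for j in range(p)],
            index=[f"S{i}" for i in range(n)],
        )
        sex = rng.integers(0, 2, size=n).astype(float)
        y = X.iloc[:, 0] * 0.8 - X.iloc[:, 1] * 0.5 + 0.4 * sex + rng.normal(size=n) * 0.3
        return X, pd.Series(y, index=X.index), sex

    def test_single_point_grid_refit_equals_direct_fit(self):
        X, y, sex = self._toy()
        cfg = ElasticNetConfig(
            alpha_grid=(0.5,), lambda_grid=(0.05,), n_folds=5, n_repeats=2, rng_seed=3
        )
        model = tune_and_train(X, y, sex, cfg)
        assert (model.alpha, model.lam) == (0.5, 0.05)
        y_res, _ = residualize(y.to_numpy(), sex)
        direct = fit_elastic_net(X.to_numpy(), y_res, 0.5, 0.05,
                                 feature_names=list(X.columns))
        assert model.weights_table.weights == direct.weights
        assert model.weights_table.intercept == direct.intercept

    def test_selection_matches_independent_cv_loop(self):
        """Hand-rolled CV loop (fit_elastic_net as fitter) reproduces the
        grid selection."""
        X, y, sex = self._toy()
        grid_a, grid_l = (0.2, 1.0), (0.05, 0.5)
        cfg = ElasticNetConfig(
            alpha_grid=grid_a, lambda_grid=grid_l, n_folds=4, n_repeats=2, rng_seed=11
        )
        model = tune_and_train(X, y, sex, cfg)

        # independent loop sharing only the fold generator and the fitter
        Xv, yv, Cv = X.to_numpy(), y.to_numpy(), sex
        ss = np.random.SeedSequence(11)
        acc = {(a, l): ([], []) for a in grid_a for l in grid_l}
        for child in ss.spawn(2):
            labels = make_folds(yv, 4, np.random.default_rng(child))
            for k in range(4):
                tr, te = labels != k, labels == k
                Xc = np.column_stack([np.ones(tr.sum()), Cv[tr]])
                b = np.linalg.lstsq(Xc, yv[tr], rcond=None)[0]
                ytr = yv[tr] - Xc @ b
                yte = yv[te] - np.column_stack([np.ones(te.sum()), Cv[te]]) @ b
                for a in grid_a:
                    for l in grid_l:
                        wt = fit_elastic_net(Xv[tr], ytr, a, l,
                                             feature_names=list(X.columns))
                        w = np.array([wt.weights[n] for n in X.columns])
                        pred = wt.intercept + Xv[te] @ w
                        mae = np.mean(np.abs(pred - yte))
                        if np.std(pred) == 0 or np.std(yte) == 0:
                            r2 = 0.0
                        else:
                            r2 = np.corrcoef(pred, yte)[0, 1] ** 2
                        acc[(a, l)][0].append(r2)
                        acc[(a, l)][1].append(mae)
        means = {g: (np.mean(v[0]), np.mean(v[1])) for g, v in acc.items()}
        best = max(means, key=lambda g: (means[g][0], -means[g][1]))
        assert (model.alpha, model.lam) == best
        for _, row in model.cv_summary.iterrows():
            g = (row["alpha"], row["lambda"])
            assert row["mean_r2"] == pytest.approx(means[g][0], abs=1e-10)
            assert row["mean_mae"] == pytest.approx(means[g][1], abs=1e-10)

    def test_deterministic_given_seed(self):
        X, y, sex = self._toy()
        cfg = ElasticNetConfig(alpha_grid=(0.3, 0.9), lambda_grid=(0.02, 0.2),
                               n_folds=4, n_repeats=2, rng_seed=21)
        m1 = tune_and_train(X, y, sex, cfg)
        m2 = tune_and_train(X, y, sex, cfg)
        assert m1.weights_table.weights == m2.weights_table.weights
        pd.testing.assert_frame_equal(m1.cv_summary, m2.cv_summary)

    def test_training_scores_match_fitted_values(self):
        X, y, sex = self._toy()
        cfg = ElasticNetConfig(alpha_grid=(0.5,), lambda_grid=(0.02,),
                               n_folds=5, n_repeats=1, rng_seed=0)
        model = tune_and_train(X, y, sex, cfg)
        scores = score_subjects(X, model.weights_table)
        assert np.allclose(scores, model.fitted_values, atol=1e-10)

    def test_too_small_folds_rejected(self):
        X, y, sex = self._toy(n=10)
        cfg = ElasticNetConfig(alpha_grid=(0.5,), lambda_grid=(0.1,), n_folds=9)
        with pytest.raises(ConfigError, match="folds"):
            tune_and_train(X, y, sex, cfg)


class TestLeakFreedom:
    def test_fold_fit_bitwise_invariant_to_heldout_corruption(self, rng):
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        C = rng.integers(0, 2, size=n).astype(float)
        train_idx = np.arange(0, 45)
        cov1, wt1 = fit_fold(X, y, C, train_idx, 0.3, 0.05)

        X2, y2, C2 = X.copy(), y.copy(), C.copy()
        X2[45:] = 1e6 * rng.normal(size=(15, p))  # corrupt held-out rows
        y2[45:] = -999.0
        C2[45:] = 7.0
        cov2, wt2 = fit_fold(X2, y2, C2, train_idx, 0.3, 0.05)
        assert np.array_equal(cov1, cov2)  # bitwise
        assert wt1.weights == wt2.weights
        assert wt1.intercept == wt2.intercept


class TestHaufe:
    def test_feature_equal_to_signal_gives_variance(self, rng):
        s = rng.normal(size=30)
        X = pd.DataFrame({"f": s})
        imp = haufe_importance(X, s)
        assert imp["f"] == pytest.approx(np.var(s, ddof=1), abs=1e-12)

    def test_brute_force_covariance_loop(self, rng):
        X = rng.normal(size=(4, 3))
        s = rng.normal(size=4)
        imp = haufe_importance(X, s)
        for j in range(3):  # independent elementwise loop, ddof=1
            acc = 0.0
            for i in range(4):
                acc += (X[i, j] - X[:, j].mean()) * (s[i] - s.mean())
            assert abs(imp.iloc[j] - acc / 3) < 1e-12

    def test_independent_noise_importance_near_zero(self, rng):
        n = 20000
        s = rng.normal(size=n)
        x = rng.normal(size=n)
        imp = haufe_importance(x[:, None], s)
        se = 1.0 / np.sqrt(n)  # cov s.e. for two unit-variance independents
        assert abs(imp.iloc[0]) < 3 * se

    def test_needs_two_rows_and_alignment(self, rng):
        with pytest.raises(DataError):
            haufe_importance(rng.normal(size=(1, 2)), [1.0])
        with pytest.raises(DataError):
            haufe_importance(rng.normal(size=(5, 2)), rng.normal(size=4))

    def test_reference_label_recorded(self, rng):
        X = rng.normal(size=(6, 2))
        imp = haufe_importance(X, X[:, 0], reference="model_prediction")
        assert imp.attrs["reference"] == "model_prediction"
        with pytest.raises(ConfigError):
            haufe_importance(X, X[:, 0], reference="something_else")
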