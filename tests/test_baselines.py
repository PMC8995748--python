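"""Comparison classifiers: least squares, Lasso, PLS and their tuning."""

import numpy as np
import pytest

from oracles import soft_threshold
from voxelsurvey import (LassoClassifier, LinearRegressionClassifier,
                         PLSClassifier, SVMClassifier, tune_baseline)


class TestLinear:
    def test_noiseless_fit_has_zero_residual(self, rng):
        X = rng.normal(size=(10, 3))
        w = np.array([1.5, -2.0, 0.5])
        y = X @ w + 0.7
        m = LinearRegressionClassifier().fit(X, y)
        assert np.allclose(m.decision_scores(X), y, atol=1e-10)

    def test_two_points_define_the_line(self):
        m = LinearRegressionClassifier().fit(np.array([[0.0], [2.0]]),
                                             np.array([1.0, 5.0]))
        assert np.isclose(m.coef_[0], 2.0) and np.isclose(m.intercept_, 1.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        m = LinearRegressionClassifier().fit(X, y)
        Xc = X - X.mean(0)
        beta = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ (y - y.mean())
        assert np.allclose(m.coef_, beta, atol=1e-8)

    def test_minimum_norm_when_underdetermined(self, rng):
        X = rng.normal(size=(4, 10))
        y = rng.normal(size=4)
        m = LinearRegressionClassifier().fit(X, y)
        # residual ~ 0 and the coefficient lies in the row space
        assert np.allclose(m.decision_scores(X), y, atol=1e-8)
        Xc = X - X.mean(0)
        proj = Xc.T @ np.linalg.pinv(Xc @ Xc.T) @ (Xc @ m.coef_)
        assert np.allclose(m.coef_, proj, atol=1e-8)


class TestLasso:
    def test_large_lambda_shrinks_to_zero(self, rng):
        X = rng.normal(size=(20, 5))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=20)
        lam = 2.0 * np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
        m = LassoClassifier(lambda_=lam * 1.0001).fit(X, y)
        assert np.all(m.beta_ == 0.0)

    def test_lambda_zero_matches_least_squares(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        lasso = LassoClassifier(lambda_=0.0).fit(X, y)
        ols = LinearRegressionClassifier().fit(X, y)
        assert np.allclose(lasso.beta_, ols.coef_, atol=1e-8)

    def test_orthonormal_design_soft_threshold_oracle(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(30, 6)))
        X = q  # columns orthonormal, zero-mean not enforced but centered below
        X = X - X.mean(0)
        # re-orthonormalize the centered design so the closed form is exact
        q, _ = np.linalg.qr(X)
        X = q
        y = rng.normal(size=30)
        yc = y - y.mean()
        lam = 0.05
        m = LassoClassifier(lambda_=lam).fit(X, y)
        z = X.T @ yc
        expected = soft_threshold(z, len(y) * lam / 2.0)
        assert np.allclose(m.beta_, expected, atol=1e-6)

    def test_objective_no_worse_than_zero_vector(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        m = LassoClassifier(lambda_=0.1).fit(X, y)
        at_zero = np.var(y) + 0.0  # (1/n)||yc||^2, beta = 0
        assert m.objective(X, y) <= at_zero + 1e-10

    def test_sparsity_non_increasing_in_lambda(self, rng):
        X = rng.normal(size=(30, 10))
        y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.normal(size=30)
        nnz = [np.count_nonzero(LassoClassifier(lambda_=lam).fit(X, y).beta_)
               for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)]
        assert nnz == sorted(nnz, reverse=True)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            LassoClassifier(lambda_=-0.1)


class TestPls:
    def test_rank_one_signal_is_captured_by_one_component(self, rng):
        t = rng.normal(size=20)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = 2.0 * t
        m = PLSClassifier(n_components=1).fit(X, y)
        assert np.abs(m.y_residual_).max() < 1e-8

    def test_full_components_match_least_squares(self, rng):
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        pls = PLSClassifier(n_components=4).fit(X, y)
        ols = LinearRegressionClassifier().fit(X, y)
        assert np.allclose(pls.decision_scores(X), ols.decision_scores(X),
                           atol=1e-6)

    def test_score_vectors_orthogonal(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        m = PLSClassifier(n_components=4).fit(X, y)
        T = m.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_x_reconstruction_holds(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = PLSClassifier(n_components=3).fit(X, y)
        Xc = X - X.mean(0)
        assert np.allclose(Xc, m.x_scores_ @ m.x_loadings_.T + m.x_residual_,
                           atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="n_components"):
            PLSClassifier(n_components=4).fit(X, rng.normal(size=6))


class TestSharedContract:
    @pytest.mark.parametrize("factory", [
        LinearRegressionClassifier,
        lambda: LassoClassifier(lambda_=0.01),
        lambda: PLSClassifier(n_components=2),
        lambda: SVMClassifier(kernel="linear", C=1.0),
    ])
    def test_fit_predict_scores_interface(self, rng, factory):
        X = np.vstack([rng.normal(-1, 0.3, size=(10, 3)),
                       rng.normal(1, 0.3, size=(10, 3))])
        y = np.repeat([-1, 1], 10)
        m = factory().fit(X, y)
        pred = m.predict(X)
        assert set(np.unique(pred)) <= {-1, 1}
        assert m.decision_scores(X).shape == (20,)
        assert m.score(X, y) == np.mean(pred == y)


class TestTuneBaseline:
    @pytest.fixture
    def linear_data(self, rng):
        X = np.vstack([rng.normal(-1, 0.2, size=(20, 4)),
                       rng.normal(1, 0.2, size=(20, 4))])
        y = np.repeat([-1, 1], 20)
        return X[::2], y[::2], X[1::2], y[1::2]

    def test_single_point_grid(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        _, params, _ = tune_baseline("lasso", Xtr, ytr, Xva, yva,
                                     grid=[{"lambda_": 0.5}])
        assert params == {"lambda_": 0.5}

    def test_lasso_small_lambda_wins_on_noiseless_linear_data(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        _, params, report = tune_baseline("lasso", Xtr, ytr, Xva, yva)
        assert params["lambda_"] <= 0.1
        assert report.accuracy == 1.0

    def test_pls_selected_component_count_is_argmax(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        model, params, report = tune_baseline("pls", Xtr, ytr, Xva, yva)
        assert 1 <= params["n_components"] <= 5
        # no other grid entry beats the selected validation accuracy
        for k in range(1, 5):
            try:
                other = PLSClassifier(n_components=k).fit(Xtr, ytr)
            except ValueError:
                continue
            assert other.score(Xva, yva) <= report.accuracy + 1e-12

    def test_unknown_kind_rejected(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        with pytest.raises(ValueError, match="unknown"):
            tune_baseline("forest", Xtr, ytr, Xva, yva)
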