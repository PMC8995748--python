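"""Comparison classifiers: linear regression, Lasso, PLS and plain SVM.

All four share one estimator contract — ``fit(X, y)``, ``predict(X)``,
``decision_scores(X)``, ``score(X, y)`` — so the comparison harness is
model-agnostic.  Continuous-output models classify by the sign of their
regression score against the {-1, +1} labels.

The regression machinery is delegated to numpy/scikit-learn (least squares,
coordinate-descent Lasso, NIPALS PLS); this module fixes the objective
conventions and the classification rule.
"""

from __future__ import annotations

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso

from .metrics import evaluate_predictions
from .svm import DEFAULT_C, DEFAULT_GAMMA, train_svm


class LinearRegressionClassifier:
    """Least-squares linear model, classifying by sign(w^T x + b).

    Minimizes sum_i (f(x_i) - y_i)^2; on underdetermined problems the
    minimum-norm coefficient vector is returned.  The intercept is handled
    by centering.
    """

    def __init__(self):
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X, y) -> "LinearRegressionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 subjects to fit")
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        coef, *_ = np.linalg.lstsq(X - x_mean, y - y_mean, rcond=None)
        self.coef_ = coef
        self.intercept_ = float(y_mean - x_mean @ coef)
        return self

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return _sign_labels(self.decision_scores(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


class LassoClassifier:
    """L1-penalized least squares, classifying by the sign of the score.

    Minimizes (1/n)||y - X beta||^2 + lambda ||beta||_1 on centered data
    (equivalently scikit-learn's objective with alpha = lambda / 2), solved
    by cyclic coordinate descent.
    """

    def __init__(self, lambda_: float = 0.01, tol: float = 1e-10,
                 max_iter: int = 50_000):
        if lambda_ < 0:
            raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
        self.lambda_ = lambda_
        self.tol = tol
        self.max_iter = max_iter
        self.beta_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X, y) -> "LassoClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.lambda_ == 0:
            # plain least squares (coordinate descent is ill-posed at 0)
            x_mean, y_mean = X.mean(axis=0), y.mean()
            beta, *_ = np.linalg.lstsq(X - x_mean, y - y_mean, rcond=None)
            self.beta_ = beta
            self.intercept_ = float(y_mean - x_mean @ beta)
            return self
        model = Lasso(
            alpha=self.lambda_ / 2.0,
            fit_intercept=True,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        model.fit(X, y)
        self.beta_ = model.coef_.copy()
        self.intercept_ = float(model.intercept_)
        return self

    def objective(self, X, y) -> float:
        """(1/n)||y - intercept - X beta||^2 + lambda ||beta||_1."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        resid = y - self.decision_scores(X)
        return float(resid @ resid / len(y) + self.lambda_ * np.abs(self.beta_).sum())

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return _sign_labels(self.decision_scores(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


class PLSClassifier:
    """Partial-least-squares regression on the label vector, sign-thresholded.

    NIPALS-style extraction of l components maximizing the covariance
    between the X scores T and the Y scores U, with deflation after each
    component; X ~ T P^T + E, Y ~ U Q^T + F.
    """

    def __init__(self, n_components: int = 2):
        if n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {n_components}")
        self.n_components = n_components
        self._pls: PLSRegression | None = None
        self._X_fit: np.ndarray | None = None
        self._y_fit: np.ndarray | None = None

    def fit(self, X, y) -> "PLSClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        cap = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > cap:
            raise ValueError(
                f"n_components ({self.n_components}) exceeds the rank bound ({cap})"
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, y.reshape(-1, 1))
        self._X_fit, self._y_fit = X, y
        return self

    # score/loading views, named by their conventional PLS symbols
    @property
    def x_scores_(self) -> np.ndarray:  # T
        return self._pls.x_scores_

    @property
    def y_scores_(self) -> np.ndarray:  # U
        return self._pls.y_scores_

    @property
    def x_loadings_(self) -> np.ndarray:  # P
        return self._pls.x_loadings_

    @property
    def y_loadings_(self) -> np.ndarray:  # Q
        return self._pls.y_loadings_

    @property
    def x_residual_(self) -> np.ndarray:  # E = Xc - T P^T
        Xc = self._X_fit - self._X_fit.mean(axis=0)
        return Xc - self.x_scores_ @ self.x_loadings_.T

    @property
    def y_residual_(self) -> np.ndarray:  # F = yc - T Q^T
        yc = (self._y_fit - self._y_fit.mean()).reshape(-1, 1)
        return yc - self.x_scores_ @ self.y_loadings_.T

    def decision_scores(self, X) -> np.ndarray:
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()

    def predict(self, X) -> np.ndarray:
        return _sign_labels(self.decision_scores(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


class SVMClassifier:
    """Plain soft-margin SVM under the shared baseline contract."""

    def __init__(self, kernel: str = "linear", C: float = DEFAULT_C,
                 gamma: float | None = DEFAULT_GAMMA):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self._model = None

    def fit(self, X, y) -> "SVMClassifier":
        self._model = train_svm(X, y, kernel=self.kernel, C=self.C,
                                gamma=self.gamma, tol=1e-3)
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self._model.decision_scores(X)

    def predict(self, X) -> np.ndarray:
        return self._model.predict(X)

    def score(self, X, y) -> float:
        return self._model.score(X, y)


def _sign_labels(scores: np.ndarray) -> np.ndarray:
    """Threshold continuous scores at 0 into {-1, +1} (0 -> +1)."""
    return np.where(np.asarray(scores) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# Grid-search tuning under the shared contract

BASELINE_KINDS = ("linear", "lasso", "pls", "svm")

#: Default hyperparameter grids per model kind.  Grids are listed in
#: tie-break order (smaller penalty / fewer components first).
DEFAULT_BASELINE_GRIDS = {
    "linear": [{}],
    "lasso": [{"lambda_": v} for v in (0.001, 0.01, 0.1, 0.5, 1.0)],
    "pls": [{"n_components": k} for k in (1, 2, 3, 4, 5)],
    "svm": None,  # filled lazily from the shared SVM grid
}


def _make_baseline(kind: str, params: dict):
    if kind == "linear":
        return LinearRegressionClassifier()
    if kind == "lasso":
        return LassoClassifier(**params)
    if kind == "pls":
        return PLSClassifier(**params)
    if kind == "svm":
        return SVMClassifier(**params)
    raise ValueError(f"unknown baseline kind {kind!r}")


def _svm_param_grid() -> list[dict]:
    from .svm import default_grid
    return [
        {"kernel": p.kernel, "C": p.C, "gamma": p.gamma}
        for p in sorted(default_grid(), key=lambda p: p.sort_key())
    ]


def baseline_grid(kind: str) -> list[dict]:
    grid = DEFAULT_BASELINE_GRIDS.get(kind)
    if kind == "svm" and grid is None:
        return _svm_param_grid()
    if grid is None:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return grid


def tune_baseline(kind: str, X_train, y_train, X_val, y_val,
                  grid: list[dict] | None = None):
    """Grid-search a baseline on the validation split.

    Returns ``(fitted_model, params, val_metrics)``; ties keep the earlier
    grid entry, so grids listed smallest-penalty-first break ties toward
    the simpler model.  PLS entries whose component count exceeds the rank
    bound of the training data are skipped.
    """
    if grid is None:
        grid = baseline_grid(kind)
    if not grid:
        raise ValueError("grid must be non-empty")
    best = None
    for params in grid:
        try:
            model = _make_baseline(kind, params).fit(X_train, y_train)
        except ValueError:
            if kind == "pls":
                continue  # component count beyond the rank bound
            raise
        report = evaluate_predictions(np.asarray(y_val), model.predict(X_val))
        if best is None or report.accuracy > best[2].accuracy:
            best = (model, params, report)
    if best is None:
        raise ValueError(f"no feasible grid point for baseline {kind!r}")
    return best
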