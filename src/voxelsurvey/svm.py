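"""Soft-margin kernel SVM and validation-set grid search.

The classifier is the standard soft-margin SVM

    min  1/2 ||w||^2 + C * sum_i eps_i
    s.t. y_i (w^T phi(x_i) + b) >= 1 - eps_i,  eps_i >= 0

with a linear or RBF kernel.  The quadratic program is solved by
scikit-learn's SVC (libsvm); the package's tests verify the returned
optimum against a direct quadratic-programming solve of the dual on small
instances.

Hyperparameters are tuned by grid search on a held-out validation set with
deterministic tie-breaking: smaller C first, then smaller gamma, then
linear before RBF.  The conventional starting point (C = 1, gamma = 0.5)
is always part of the default grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .metrics import MetricsReport, evaluate_predictions

DEFAULT_C = 1.0
DEFAULT_GAMMA = 0.5

#: Grid-search ranges (linear ignores gamma).
DEFAULT_C_RANGE = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_RANGE = (0.001, 0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class GridPoint:
    kernel: str
    C: float
    gamma: float | None = None  # None for linear

    def sort_key(self):
        # smaller C, then smaller gamma, then linear before rbf
        return (self.C, self.gamma if self.gamma is not None else 0.0,
                0 if self.kernel == "linear" else 1)


def default_grid() -> list[GridPoint]:
    """Linear x C plus RBF x C x gamma; includes (C=1, gamma=0.5)."""
    grid = [GridPoint("linear", C) for C in DEFAULT_C_RANGE]
    grid += [GridPoint("rbf", C, g) for C in DEFAULT_C_RANGE for g in DEFAULT_GAMMA_RANGE]
    return grid


class SvmModel:
    """A fitted soft-margin SVM (thin wrapper over sklearn SVC)."""

    def __init__(self, kernel: str, C: float, gamma: float | None, svc: SVC,
                 X_train: np.ndarray, y_train: np.ndarray):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self._svc = svc
        self._X_train = X_train
        self._y_train = y_train

    @property
    def support_indices(self) -> np.ndarray:
        return self._svc.support_

    @property
    def dual_coef(self) -> np.ndarray:
        """Signed dual coefficients y_i * alpha_i of the support vectors."""
        return self._svc.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self._svc.intercept_[0])

    @property
    def coef(self) -> np.ndarray:
        """Primal weight vector w (linear kernel only)."""
        if self.kernel != "linear":
            raise AttributeError("w is only explicit for the linear kernel")
        return self._svc.coef_.ravel()

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float)).astype(int)

    def decision_scores(self, X) -> np.ndarray:
        """Signed distances f(x) = w^T phi(x) + b for ROC analysis."""
        return self._svc.decision_function(np.asarray(X, dtype=float))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def primal_objective(self) -> float:
        """1/2 ||w||^2 + C * sum(slacks) at the training solution.

        Evaluated in the kernel-induced feature space via the dual
        coefficients, so it is available for the RBF kernel as well.
        """
        sv = self._X_train[self._svc.support_]
        beta = self.dual_coef  # y_i alpha_i
        K = self._kernel_matrix(sv, sv)
        w_norm_sq = float(beta @ K @ beta)
        scores = self.decision_scores(self._X_train)
        slack = np.maximum(0.0, 1.0 - self._y_train * scores)
        return 0.5 * w_norm_sq + self.C * float(slack.sum())

    def _kernel_matrix(self, A, B) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-self.gamma * sq)


def train_svm(
    X_train,
    y_train,
    kernel: str = "linear",
    C: float = DEFAULT_C,
    gamma: float | None = DEFAULT_GAMMA,
    tol: float = 1e-6,
) -> SvmModel:
    """Fit a soft-margin SVM on {-1, +1}-labelled data.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    C : float
        Penalty factor (> 0) on the margin-violation slacks.
    gamma : float, optional
        RBF width parameter (> 0); ignored for the linear kernel.
    tol : float
        Solver stopping tolerance.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if kernel == "rbf" and (gamma is None or gamma <= 0):
        raise ValueError(f"gamma must be > 0 for the rbf kernel, got {gamma}")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")

    svc = SVC(
        kernel=kernel,
        C=C,
        gamma=gamma if kernel == "rbf" else "scale",
        tol=tol,
        shrinking=True,
    )
    svc.fit(X_train, y_train)
    return SvmModel(
        kernel=kernel,
        C=C,
        gamma=gamma if kernel == "rbf" else None,
        svc=svc,
        X_train=X_train,
        y_train=y_train,
    )


def grid_search(
    X_train,
    y_train,
    X_val,
    y_val,
    grid: list[GridPoint] | None = None,
) -> tuple[GridPoint, MetricsReport, SvmModel]:
    """Pick the grid point maximizing validation accuracy.

    Ties are broken deterministically: smaller C, then smaller gamma, then
    linear before RBF.  Returns the winning parameters, the validation
    metrics at that point, and the fitted model.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    y_val = np.asarray(y_val, dtype=int)

    best = None  # (acc, point, report, model)
    for point in sorted(grid, key=GridPoint.sort_key):
        model = train_svm(
            X_train, y_train, kernel=point.kernel, C=point.C,
            gamma=point.gamma, tol=1e-3,
        )
        report = evaluate_predictions(y_val, model.predict(X_val))
        if best is None or report.accuracy > best[0]:
            best = (report.accuracy, point, report, model)
    return best[1], best[2], best[3]
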