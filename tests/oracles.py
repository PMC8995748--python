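"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the SVM oracle is a
direct quadratic-programming solve of the soft-margin dual, the AUC oracle
is the Mann-Whitney rank statistic, and the soft-threshold oracle is the
closed-form Lasso solution on orthonormal designs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def svm_dual_optimum(X, y, kernel: str, C: float, gamma: float | None = None) -> float:
    """Brute-force QP solve of the soft-margin SVM dual.

    maximize  sum(a) - 1/2 a^T (yy^T * K) a
    s.t.      0 <= a_i <= C,  sum a_i y_i = 0

    By strong duality the optimum equals the primal objective
    1/2||w||^2 + C*sum(slacks).  Multi-start SLSQP; returns the best value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if kernel == "linear":
        K = X @ X.T
    else:
        sq = np.sum(X**2, 1)[:, None] + np.sum(X**2, 1)[None, :] - 2 * X @ X.T
        K = np.exp(-gamma * sq)
    Q = (y[:, None] * y[None, :]) * K

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = None
    for s in range(4):
        a0 = np.random.default_rng(s).uniform(0, min(C, 1.0), n)
        a0 = np.clip(a0 - y * (a0 @ y) / n, 0, C)
        res = minimize(fun, a0, jac=jac, bounds=[(0, C)] * n, constraints=cons,
                       method="SLSQP", options={"maxiter": 3000, "ftol": 1e-15})
        if best is None or res.fun < best:
            best = res.fun
    return -best


def mann_whitney_auc(scores, y_true, positive: int = 1) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = scores[y_true == positive]
    neg = scores[y_true != positive]
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Closed-form Lasso coordinate solution: S(z, t) = sign(z)(|z|-t)_+."""
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def dense_similarity(points: np.ndarray) -> np.ndarray:
    """Direct O(n^2) squared-distance matrix (loop-free but independent of
    the package's block path)."""
    diff_m = points[:, 0][:, None] - points[:, 0][None, :]
    diff_n = points[:, 1][:, None] - points[:, 1][None, :]
    return diff_m**2 + diff_n**2
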