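"""SMO solver for the class-weighted soft-margin linear SVM dual.

Solves

    min_a  1/2 sum_ij a_i a_j y_i y_j x_i'x_j - sum_i a_i
    s.t.   0 <= a_i <= C_i,   sum_i a_i y_i = 0

by sequential minimal optimization with maximal-violating-pair working-set
selection (the libsvm strategy). The linear kernel lets the weight vector
w = sum_i a_i y_i x_i be maintained directly, so each pair update costs
O(n p). The bias is recovered from the KKT conditions as the midpoint of the
violating-pair bounds. Warm starts (an initial feasible alpha) make
leave-one-group-out refits converge in a handful of iterations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_svm_dual"]

DEFAULT_EPS = 1e-3  # KKT violation gap m - M at which to stop
MAX_ITER = 200_000


@njit(cache=True)
def _smo(X, y, Cvec, alpha, eps, max_iter):  # pragma: no cover - jit kernel
    n, p = X.shape
    w = X.T @ (alpha * y)  # w = sum_i a_i y_i x_i
    f = X @ w  # f_i = w'x_i
    qii = (X * X).sum(axis=1)

    b = 0.0
    for it in range(max_iter):
        # maximal violating pair: m over I_up, M over I_low of y_i - f_i;
        # alphas within rounding dust of a bound count as at the bound
        m_val = -1e300
        M_val = 1e300
        i_up = -1
        i_low = -1
        for i in range(n):
            tau = 1e-12 * (1.0 + Cvec[i])
            if alpha[i] < tau:
                alpha[i] = 0.0
            elif alpha[i] > Cvec[i] - tau:
                alpha[i] = Cvec[i]
            v = y[i] - f[i]
            up = (y[i] > 0 and alpha[i] < Cvec[i]) or (y[i] < 0 and alpha[i] > 0.0)
            low = (y[i] > 0 and alpha[i] > 0.0) or (y[i] < 0 and alpha[i] < Cvec[i])
            if up and v > m_val:
                m_val = v
                i_up = i
            if low and v < M_val:
                M_val = v
                i_low = i
        b = (m_val + M_val) / 2.0  # for free SVs, y_i - w'x_i == b
        if i_up < 0 or i_low < 0 or m_val - M_val < eps:
            return w, b, it
        i, j = i_up, i_low
        xi = X[i]
        xj = X[j]
        eta = qii[i] + qii[j] - 2.0 * (xi @ xj)
        if eta <= 1e-12:
            eta = 1e-12
        aj_old = alpha[j]
        ai_old = alpha[i]
        aj = aj_old + y[j] * ((f[i] - y[i]) - (f[j] - y[j])) / eta
        # box bounds preserving alpha_i y_i + alpha_j y_j
        if y[i] != y[j]:
            L = max(0.0, aj_old - ai_old)
            H = min(Cvec[j], Cvec[i] + aj_old - ai_old)
        else:
            L = max(0.0, ai_old + aj_old - Cvec[i])
            H = min(Cvec[j], ai_old + aj_old)
        if aj < L:
            aj = L
        elif aj > H:
            aj = H
        ai = ai_old + y[i] * y[j] * (aj_old - aj)
        di = (ai - ai_old) * y[i]
        dj = (aj - aj_old) * y[j]
        if di == 0.0 and dj == 0.0:
            return w, b, it
        alpha[i] = ai
        alpha[j] = aj
        v = di * xi + dj * xj
        w += v
        f += X @ v
    return w, b, max_iter


def solve_svm_dual(
    X: np.ndarray,
    y: np.ndarray,
    C_pos: float,
    C_neg: float,
    alpha0: np.ndarray | None = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Return (w, b, alpha) for the class-weighted hinge-loss linear SVM.

    ``alpha0`` warm-starts the solver; it is clipped to the box and projected
    back onto the equality constraint before iterating.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    yf = np.ascontiguousarray(y, dtype=np.float64)
    n = X.shape[0]
    Cvec = np.where(yf > 0, C_pos, C_neg)
    if alpha0 is None:
        alpha = np.zeros(n)
    else:
        alpha = np.clip(np.asarray(alpha0, dtype=np.float64), 0.0, Cvec)
        # restore sum_i alpha_i y_i = 0, touching as few coordinates as
        # possible: shrink the largest alphas on the heavier side
        imbalance = float((alpha * yf).sum())
        side = 1.0 if imbalance > 0 else -1.0
        need = abs(imbalance)
        if need > 0:
            order = np.argsort(-alpha)
            for i in order:
                if need <= 0:
                    break
                if yf[i] == side and alpha[i] > 0:
                    take = min(alpha[i], need)
                    alpha[i] -= take
                    need -= take
    w, b, _ = _smo(X, yf, Cvec, alpha, eps, max_iter)
    return w, b, alpha
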