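"""L1-penalized fractional-response logistic solver.

Minimises, for each penalty ``lam`` on a descending warm-started path,

    f(b0, b) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
               + lam * sum_j |b_j|,        eta = b0 + X b,

with y_i in [0, 1] (fractional responses are valid binomial means) and an
unpenalised intercept. The algorithm is the standard IRLS + cyclic
coordinate-descent scheme (as in glmnet / lassoglm): at each outer step a
weighted least-squares surrogate is built from the current probabilities
and solved by soft-thresholded coordinate updates.

The inner kernel is compiled with numba when available; a pure-Python
fallback with identical semantics is used otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_l1_path", "fit_l1_single"]

_WMIN = 1e-5


def _cd_path_py(X, y, lambdas, tol, max_outer, max_inner, Binit, B0init,
                use_init):
    n, p = X.shape
    nlam = lambdas.shape[0]
    B = np.zeros((nlam, p))
    B0 = np.zeros(nlam)
    beta = np.zeros(p)
    b0 = 0.0
    xsq = np.empty(p)
    active = np.zeros(p, np.bool_)
    for il in range(nlam):
        lam = lambdas[il]
        if use_init:
            # warm start from a reference solution (e.g. the fit on a
            # superset of the rows) instead of the previous lambda
            for j in range(p):
                beta[j] = Binit[il, j]
                active[j] = beta[j] != 0.0
            b0 = B0init[il]
        for _outer in range(max_outer):
            eta = b0 + X @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = prob * (1.0 - prob)
            for i in range(n):
                if w[i] < _WMIN:
                    w[i] = _WMIN
            z = eta + (y - prob) / w
            r = z - eta  # residual of the working model
            sw = w.sum()
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                xsq[j] = s / n
            # inner CD on the weighted-least-squares surrogate:
            # full sweeps alternate with sweeps over the active set only
            outer_delta = 0.0
            full_pass = True
            for _inner in range(max_inner):
                maxd = 0.0
                db0 = 0.0
                for i in range(n):
                    db0 += w[i] * r[i]
                db0 /= sw
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                if abs(db0) > maxd:
                    maxd = abs(db0)
                for j in range(p):
                    if not full_pass and not active[j]:
                        continue
                    if xsq[j] <= 0.0:
                        continue
                    g = 0.0
                    for i in range(n):
                        g += w[i] * X[i, j] * r[i]
                    g = g / n + xsq[j] * beta[j]
                    if g > lam:
                        new = (g - lam) / xsq[j]
                    elif g < -lam:
                        new = (g + lam) / xsq[j]
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= d * X[i, j]
                        beta[j] = new
                        if abs(d) > maxd:
                            maxd = abs(d)
                    active[j] = new != 0.0
                if maxd > outer_delta:
                    outer_delta = maxd
                if full_pass:
                    if maxd < tol:
                        break  # full sweep already converged
                    full_pass = False
                elif maxd < tol:
                    full_pass = True  # re-check every coordinate once
            if outer_delta < tol * 10.0:
                break
        B[il] = beta
        B0[il] = b0
    return B, B0


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _cd_path = njit(cache=True, fastmath=False)(_cd_path_py)
except Exception:  # pragma: no cover
    _cd_path = _cd_path_py


def fit_l1_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-5,
    max_outer: int = 25,
    max_inner: int = 60,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the full penalty path (descending ``lambdas``, warm starts).

    ``init`` may carry a reference path solution ``(coefs, intercepts)``
    to warm-start each penalty from (used by the inner cross-validation
    loops, whose training rows are near-supersets of each other).
    Returns ``(coefs, intercepts)`` with ``coefs`` of shape
    ``(len(lambdas), n_features)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if np.any(lambdas < 0):
        raise ValueError("lambda must be nonnegative")
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda path must be non-increasing")
    if init is None:
        Binit = np.zeros((1, X.shape[1]))
        B0init = np.zeros(1)
        use_init = False
    else:
        Binit = np.ascontiguousarray(init[0], dtype=np.float64)
        B0init = np.ascontiguousarray(init[1], dtype=np.float64)
        if Binit.shape != (lambdas.size, X.shape[1]):
            raise ValueError("init shape mismatch")
        use_init = True
    return _cd_path(X, y, lambdas, tol, max_outer, max_inner, Binit, B0init,
                    use_init)


def fit_l1_single(
    X: np.ndarray, y: np.ndarray, lam: float, **kw
) -> tuple[np.ndarray, float]:
    """Fit a single penalty value; returns ``(coef, intercept)``."""
    B, B0 = fit_l1_path(X, y, np.array([float(lam)]), **kw)
    return B[0], float(B0[0])
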