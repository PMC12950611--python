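"""Nonnegative least squares core used by the constrained deconvolution.

The decay-shape constraints (nonnegativity and monotone decrease of
h = B c) make the coefficient estimate a convex quadratic program.  It is
solved through its dual, which is a nonnegative least-squares problem
``min_{x >= 0} || M x + v ||^2`` whose active set is at most the number of
Laguerre coefficients, while the number of constraint columns is ~2x the
record length.  A Lawson-Hanson active-set iteration specialized to this
wide, low-rank geometry is JIT-compiled with numba; scipy's reference NNLS
is kept as a verification oracle in the tests and as a runtime fallback if
the iteration limit is hit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nnls_wide", "nnls_wide_ref"]


@njit(cache=True)
def _nnls_lawson_hanson(M, v, tol_rel, max_iter):  # pragma: no cover - compiled
    r, m = M.shape
    x = np.zeros(m)
    res = v.copy()  # residual M x + v
    P = np.empty(4 * r, np.int64)  # passive set; active set size <= r
    k = 0
    g0 = 0.0
    for j in range(m):
        s = 0.0
        for i in range(r):
            s += M[i, j] * v[i]
        if abs(s) > g0:
            g0 = abs(s)
    tol = tol_rel * g0
    for _ in range(max_iter):
        jbest = -1
        gbest = -tol
        for j in range(m):
            inP = False
            for q in range(k):
                if P[q] == j:
                    inP = True
                    break
            if inP:
                continue
            s = 0.0
            for i in range(r):
                s += M[i, j] * res[i]
            if s < gbest:
                gbest = s
                jbest = j
        if jbest < 0:
            return x, True
        if k >= P.size:
            return x, False
        P[k] = jbest
        k += 1
        while True:
            T = np.zeros((k, k))
            rhs = np.zeros(k)
            for a in range(k):
                ja = P[a]
                for b in range(a, k):
                    jb = P[b]
                    s = 0.0
                    for i in range(r):
                        s += M[i, ja] * M[i, jb]
                    T[a, b] = s
                    T[b, a] = s
                s = 0.0
                for i in range(r):
                    s += M[i, ja] * v[i]
                rhs[a] = -s
            sol = np.linalg.solve(T, rhs)
            allpos = True
            for a in range(k):
                if sol[a] <= 0.0:
                    allpos = False
                    break
            if allpos:
                for a in range(k):
                    x[P[a]] = sol[a]
                for i in range(r):
                    s = v[i]
                    for a in range(k):
                        s += M[i, P[a]] * sol[a]
                    res[i] = s
                break
            amin = 1.0e300
            for a in range(k):
                if sol[a] <= 0.0:
                    xp = x[P[a]]
                    denom = xp - sol[a]
                    if denom > 0.0:
                        step = xp / denom
                        if step < amin:
                            amin = step
            if amin >= 1.0e300:
                amin = 0.0
            nk = 0
            for a in range(k):
                xa = x[P[a]] + amin * (sol[a] - x[P[a]])
                if xa < 1e-14:
                    xa = 0.0
                x[P[a]] = xa
                if xa > 0.0:
                    P[nk] = P[a]
                    nk += 1
                else:
                    x[P[a]] = 0.0
            k = nk
            if k == 0:
                for i in range(r):
                    res[i] = v[i]
                break
    return x, False


def nnls_wide_ref(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Reference solution of min_{x>=0} ||M x + v||^2 via scipy."""
    from scipy.optimize import nnls

    x, _ = nnls(np.ascontiguousarray(M), -np.asarray(v, float))
    return x


def nnls_wide(M: np.ndarray, v: np.ndarray, tol_rel: float = 1e-10,
              max_iter: int = 500) -> np.ndarray:
    """Solve min_{x >= 0} || M x + v ||^2 for wide, low-rank M.

    Falls back to scipy's NNLS if the active-set iteration does not
    terminate within ``max_iter`` rounds (essentially never in practice).
    """
    M = np.ascontiguousarray(M, dtype=np.float64)
    v = np.ascontiguousarray(v, dtype=np.float64)
    x, ok = _nnls_lawson_hanson(M, v, tol_rel, max_iter)
    if not ok:
        x = nnls_wide_ref(M, v)
    return x
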