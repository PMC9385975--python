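"""Warm-startable epsilon-SVR solver for the inner cross-validation loops.

Nested LOOCV with a 15 x 15 hyperparameter grid evaluates millions of
small SVR problems that differ by one held-out sample or one grid step.
A generic solver re-solves each from scratch; this module implements the
standard SMO algorithm (maximal-violating-pair working-set selection) on
the dual coefficients beta_i = alpha_i - alpha_i* in [-C, C], operating
on a precomputed kernel, so that

* the solution for cost C_k seeds the solve for C_{k+1} on the same
  kernel, and
* the full-sample solution seeds every leave-one-out fold (remove the
  held-out coefficient, restore the equality constraint, re-optimize).

Solutions agree with scikit-learn's SVR to within the shared stopping
tolerance (asserted in the test suite); the final per-fold models are
still fit with scikit-learn.  Requires epsilon > 0 (the pair-selection
rule relies on the epsilon-wide dual gap between a coefficient's two
movement directions).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["svr_solve", "loocv_sq_errors"]


@njit(cache=True, fastmath=False)
def _smo(K, y, C, eps, tol, beta, h, excl, max_iter):
    """Minimize 0.5 b'Kb - y'b + eps*||b||_1 s.t. sum(b)=0, |b_i|<=C.

    ``beta``/``h`` (= K @ beta) are updated in place from a feasible warm
    start; ``excl`` >= 0 freezes that index at zero (leave-one-out).
    Returns the iteration count.
    """
    n = len(y)
    for it in range(max_iter):
        # select maximal violating pair: u may increase, l may decrease
        up_best = np.inf
        low_best = np.inf
        u = -1
        l = -1
        for i in range(n):
            if i == excl:
                continue
            g = h[i] - y[i]
            b = beta[i]
            if b < C:  # can increase beta_i
                v = g + (eps if b >= 0.0 else -eps)
                if v < up_best:
                    up_best = v
                    u = i
            if b > -C:  # can decrease beta_i
                v = -g + (eps if b <= 0.0 else -eps)
                if v < low_best:
                    low_best = v
                    l = i
        if u < 0 or l < 0 or up_best + low_best >= -tol:
            return it
        # exact line search along beta_u += d, beta_l -= d, d in [0, dmax]
        bu = beta[u]
        bl = beta[l]
        dmax = min(C - bu, bl + C)
        eta = K[u, u] + K[l, l] - 2.0 * K[u, l]
        if eta < 1e-12:
            eta = 1e-12
        base = h[u] - h[l] - y[u] + y[l]
        # kinks where a coefficient crosses zero
        k1 = -bu if bu < 0.0 else 0.0   # beta_u + d = 0
        k2 = bl if bl > 0.0 else 0.0    # beta_l - d = 0
        lo_k = min(k1, k2)
        hi_k = max(k1, k2)
        d = 0.0
        found = False
        seg_lo = 0.0
        for seg in range(3):
            if seg == 0:
                seg_hi = lo_k if lo_k > 0.0 else 0.0
            elif seg == 1:
                seg_hi = hi_k if hi_k > 0.0 else 0.0
            else:
                seg_hi = dmax
            if seg_hi > dmax:
                seg_hi = dmax
            if seg_hi <= seg_lo:
                seg_lo = seg_hi
                continue
            mid = 0.5 * (seg_lo + seg_hi)
            su = 1.0 if bu + mid > 0.0 else -1.0
            sl = 1.0 if bl - mid > 0.0 else -1.0
            slope0 = base + eps * (su - sl)
            d_star = -slope0 / eta
            if d_star <= seg_lo:
                d = seg_lo
                found = True
                break
            if d_star < seg_hi:
                d = d_star
                found = True
                break
            seg_lo = seg_hi
        if not found:
            d = dmax
        if d <= 0.0:
            return it
        beta[u] = bu + d
        beta[l] = bl - d
        for j in range(n):
            h[j] += d * (K[u, j] - K[l, j])
    return max_iter


@njit(cache=True)
def _bias(K, y, C, eps, beta, h, excl):
    """Prediction bias b of f(x) = sum_j beta_j K(x, j) + b.

    Follows libsvm's rho rule on the equivalent 2n-variable problem:
    average the implied bias over free dual variables; with none free,
    take the midpoint of the feasible bias interval.
    """
    n = len(y)
    sum_free = 0.0
    nr_free = 0
    ub = np.inf
    lb = -np.inf
    margin = 1e-8 * (1.0 + C)
    for i in range(n):
        if i == excl:
            continue
        b = beta[i]
        g_pos = h[i] + eps - y[i]    # gradient of the alpha_i variable
        g_neg = h[i] - eps - y[i]    # -gradient of the alpha_i* variable
        # alpha_i = max(beta, 0): free / at 0 / at C
        if b >= C - margin:
            lb = max(lb, g_pos)
        elif b > margin:
            sum_free += g_pos
            nr_free += 1
        else:
            ub = min(ub, g_pos)
        # alpha_i* = max(-beta, 0): free / at 0 / at C
        if b <= -C + margin:
            ub = min(ub, g_neg)
        elif b < -margin:
            sum_free += g_neg
            nr_free += 1
        else:
            lb = max(lb, g_neg)
    if nr_free > 0:
        rho = sum_free / nr_free
    else:
        rho = 0.5 * (ub + lb)
    return -rho


@njit(cache=True)
def _loocv_core(K, y, C, eps, tol, beta0, h0, max_iter):
    n = len(y)
    it_full = _smo(K, y, C, eps, tol, beta0, h0, -1, max_iter)
    sq = np.empty(n)
    beta = np.empty(n)
    h = np.empty(n)
    for i in range(n):
        for j in range(n):
            beta[j] = beta0[j]
            h[j] = h0[j]
        bi = beta[i]
        if bi != 0.0:
            beta[i] = 0.0
            for j in range(n):
                h[j] -= bi * K[i, j]
            # restore sum(beta) = 0 within the box
            rem = bi
            for j in range(n):
                if j == i or rem == 0.0:
                    continue
                if rem > 0.0:
                    room = C - beta[j]
                    step = rem if rem < room else room
                else:
                    room = -C - beta[j]
                    step = rem if rem > room else room
                if step != 0.0:
                    beta[j] += step
                    rem -= step
                    for m in range(n):
                        h[m] += step * K[j, m]
        _smo(K, y, C, eps, tol, beta, h, i, max_iter)
        b = _bias(K, y, C, eps, beta, h, i)
        r = h[i] + b - y[i]
        sq[i] = r * r
    return sq, it_full


def svr_solve(K: np.ndarray, y: np.ndarray, C: float, eps: float,
              tol: float = 1e-3, beta: np.ndarray | None = None,
              max_iter: int = 200_000) -> tuple[np.ndarray, float]:
    """Solve one epsilon-SVR on a precomputed kernel; returns (beta, bias)."""
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    n = len(y)
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if beta is None:
        beta = np.zeros(n)
        h = np.zeros(n)
    else:
        beta = np.clip(np.asarray(beta, dtype=np.float64).copy(), -C, C)
        h = K @ beta
    _smo(K, y, C, eps, tol, beta, h, -1, max_iter)
    return beta, float(_bias(K, y, C, eps, beta, h, -1))


def loocv_sq_errors(K: np.ndarray, y: np.ndarray, C: float, eps: float,
                    tol: float = 1e-3, beta_init: np.ndarray | None = None,
                    max_iter: int = 200_000
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out squared errors of epsilon-SVR on a precomputed kernel.

    Solves the full problem (optionally warm-started from ``beta_init``,
    e.g. the solution at the previous cost value), then re-optimizes each
    fold from the full-sample solution.  Returns (squared errors, the
    full-sample beta for warm-start chaining).
    """
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    n = len(y)
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if beta_init is None:
        beta0 = np.zeros(n)
        h0 = np.zeros(n)
    else:
        beta0 = np.clip(np.asarray(beta_init, dtype=np.float64).copy(),
                        -C, C)
        if abs(float(beta0.sum())) > 1e-9:  # infeasible warm start
            beta0 = np.zeros(n)
        h0 = K @ beta0
    sq, _ = _loocv_core(K, y, C, eps, tol, beta0, h0, max_iter)
    return sq, beta0
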