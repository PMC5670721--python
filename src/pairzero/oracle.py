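"""High-precision reference solvers, independent of the ADMM implementation.

Used as the ground truth in the convergence benchmark and in tests.  The
constrained lasso reference is an accelerated proximal-gradient (FISTA with
adaptive restart) whose proximal step handles the L1 penalty and the
sum-to-zero constraint jointly and exactly:

    prox(v) = argmin_z  t ||z||_1 + (1/2) ||z - v||^2   s.t.  1'z = 0
            = S_t(v - mu * 1),

where the shift mu is the root of the monotone piecewise-linear function
``g(mu) = sum_j S_t(v_j - mu)``, found by bisection to machine precision.
Because the problems of interest have more observations than genes, the
objective is strongly convex on the constraint set and restart-FISTA
converges linearly, so solutions at 1e-12-level accuracy are cheap.

A linear program (via scipy HiGHS) provides the minimum-L1 pair
decomposition oracle on small p for validating the peeling algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "prox_l1_sum_zero",
    "reference_constrained_lasso",
    "reference_lasso",
    "min_l1_decomposition_lp",
]


def prox_l1_sum_zero(v: np.ndarray, t: float, tol: float = 1e-15) -> np.ndarray:
    """Exact prox of t*||.||_1 restricted to the sum-to-zero hyperplane."""
    v = np.asarray(v, dtype=float)
    if t < 0:
        raise ValueError("threshold must be non-negative")

    def shifted(mu: float) -> np.ndarray:
        return np.sign(v - mu) * np.maximum(np.abs(v - mu) - t, 0.0)

    lo = float(v.min()) - t - 1.0
    hi = float(v.max()) + t + 1.0
    # g(mu) = sum(shifted(mu)) is continuous and non-increasing, positive at
    # lo and negative at hi; bisect until the bracket collapses.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = float(shifted(mid).sum())
        if g > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(1.0, abs(mid)):
            break
    z = shifted(0.5 * (lo + hi))
    return z - z.mean()  # remove last-bit residual


def _fista(
    gram: np.ndarray,
    lin: np.ndarray,
    lam: float,
    prox,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Restart-FISTA on (1/2) x'Gx - lin'x + lam||x||_1 with a custom prox."""
    L = float(np.linalg.eigvalsh(gram)[-1]) + 1e-12
    step = 1.0 / L
    x = np.zeros_like(lin)
    y = x.copy()
    theta = 1.0
    for it in range(max_iter):
        grad = gram @ y - lin
        x_new = prox(y - step * grad, lam * step)
        if (y - x_new) @ (x_new - x) > 0:  # adaptive restart
            theta = 1.0
            y = x.copy()
            grad = gram @ y - lin
            x_new = prox(y - step * grad, lam * step)
        theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta**2))
        y = x_new + ((theta - 1.0) / theta_new) * (x_new - x)
        x, theta = x_new, theta_new
        if it % 20 == 0:
            gmap = x - prox(x - step * (gram @ x - lin), lam * step)
            if np.linalg.norm(gmap) * L <= tol:
                break
    return x


def reference_constrained_lasso(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    tol: float = 1e-11,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Reference minimizer of (1/2)||Ax-b||^2 + lam||x||_1 s.t. sum(x)=0."""
    A = np.atleast_2d(np.asarray(design, float))
    b = np.asarray(response, float).ravel()
    gram = A.T @ A
    lin = A.T @ b
    return _fista(gram, lin, lam, prox_l1_sum_zero, tol, max_iter)


def reference_lasso(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    tol: float = 1e-11,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Reference minimizer of the plain lasso (1/2)||Ax-b||^2 + lam||x||_1."""
    A = np.atleast_2d(np.asarray(design, float))
    b = np.asarray(response, float).ravel()
    gram = A.T @ A
    lin = A.T @ b

    def prox(v: np.ndarray, t: float) -> np.ndarray:
        return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)

    return _fista(gram, lin, lam, prox, tol, max_iter)


def min_l1_decomposition_lp(beta: np.ndarray) -> float:
    """Minimum of ||alpha||_1 over pair representations of beta, by LP.

    Splits each alpha_jk into positive and negative parts and solves
    min 1'(a+ + a-) subject to M(a+ - a-) = beta, where column (j,k) of M
    has +1 at row j and -1 at row k.  Intended for small p (the LP has
    p(p-1) variables); serves as an independent check of peeling.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    p = beta.size
    if abs(beta.sum()) > 1e-9 * max(1.0, np.abs(beta).sum()):
        raise ValueError("beta must sum to zero")
    jj, kk = np.triu_indices(p, k=1)
    q = jj.size
    M = np.zeros((p, q))
    M[jj, np.arange(q)] = 1.0
    M[kk, np.arange(q)] = -1.0
    A_eq = np.hstack([M, -M])
    res = linprog(
        c=np.ones(2 * q),
        A_eq=A_eq,
        b_eq=beta,
        bounds=[(0, None)] * (2 * q),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP oracle failed: {res.message}")
    return float(res.fun)
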