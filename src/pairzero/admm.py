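"""ADMM solver for the lasso with a linear equality constraint.

Solves

    min_x  (1/2) ||A x - b||_2^2 + lambda * sum_{j penalized} |x_j|
    s.t.   C x = d

by splitting ``x = z`` and stacking the two equality constraints
``B x + D z = dbar`` with ``B = [C; I]``, ``D = [0; -I]``.  The scaled-dual
iteration alternates

    x  <- (E'E + rho I)^{-1} (A'b + rho (z - C' u1 + C' d - u2)),
           E = [A; sqrt(rho) C]
    z  <- soft_threshold(x + u2, lambda / rho)   (penalized coordinates)
    u1 <- u1 + (C x - d);   u2 <- u2 + (x - z)

and stops when the primal residual ||(Cx - d, x - z)||_2 and dual residual
rho ||z - z_old||_2 fall below tolerances combining an absolute and a
relative part.  The x-update factorization does not depend on lambda and is
cached, via a Cholesky factor of the m x m normal matrix when the design is
tall, or through the matrix inversion lemma on the (n+1) x (n+1) Gram of E
rows when the design is wide (m > n + 1).

With the constraint row zeroed the same iteration is a plain lasso, used
for the unconstrained baselines.  Warm starts across a decreasing lambda
grid give the solution path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model_core import GeneCoefficients

__all__ = [
    "ConstrainedLassoProblem",
    "ADMMConfig",
    "ADMMSolution",
    "SolutionPath",
    "soft_threshold",
    "admm_fit",
    "unconstrained_fit",
    "lambda_max",
    "lambda_grid",
    "solve_path",
    "build_pair_design",
    "l1_objective",
]


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Elementwise shrinkage sign(v) * max(|v| - t, 0)."""
    if t < 0:
        raise ValueError(f"threshold must be non-negative, got {t}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


@dataclass(frozen=True)
class ConstrainedLassoProblem:
    """Design, response, equality constraint and penalty exclusions.

    ``design`` is n x m; an unpenalized intercept, when present, is the
    all-ones first column with a zero in ``constraint_row`` and False in
    ``penalize``.
    """

    design: np.ndarray
    response: np.ndarray
    constraint_row: np.ndarray
    constraint_value: float = 0.0
    penalize: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.design, dtype=float))
        b = np.asarray(self.response, dtype=float).ravel()
        C = np.asarray(self.constraint_row, dtype=float).ravel()
        n, m = A.shape
        if b.shape != (n,):
            raise ValueError(f"response length {b.size} != design rows {n}")
        if C.shape != (m,):
            raise ValueError(f"constraint row length {C.size} != design columns {m}")
        pen = self.penalize
        pen = np.ones(m, bool) if pen is None else np.asarray(pen, bool).ravel()
        if pen.shape != (m,):
            raise ValueError("penalize flags must match design columns")
        if np.any(C[~pen] != 0.0) and np.any(~pen):
            # unpenalized intercept must also be unconstrained
            raise ValueError("constraint row must be zero on unpenalized columns")
        object.__setattr__(self, "design", A)
        object.__setattr__(self, "response", b)
        object.__setattr__(self, "constraint_row", C)
        object.__setattr__(self, "constraint_value", float(self.constraint_value))
        object.__setattr__(self, "penalize", pen)

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def m(self) -> int:
        return self.design.shape[1]

    @property
    def has_intercept(self) -> bool:
        return bool(np.any(~self.penalize))

    @classmethod
    def from_log_expression(
        cls,
        log_expr: np.ndarray,
        response: np.ndarray,
        intercept: bool = False,
        constrained: bool = True,
    ) -> "ConstrainedLassoProblem":
        """Sum-to-zero problem on a samples x genes log-expression matrix.

        With ``constrained=False`` the constraint row is zero and the fit is
        an ordinary lasso on the same design.
        """
        X = np.atleast_2d(np.asarray(log_expr, dtype=float))
        n, p = X.shape
        ones = float(constrained)
        if intercept:
            design = np.column_stack([np.ones(n), X])
            C = np.concatenate([[0.0], np.full(p, ones)])
            pen = np.concatenate([[False], np.ones(p, bool)])
        else:
            design = X
            C = np.full(p, ones)
            pen = np.ones(p, bool)
        return cls(design=design, response=response, constraint_row=C, penalize=pen)


@dataclass(frozen=True)
class ADMMConfig:
    """Penalty parameter and stopping tolerances for the ADMM iteration."""

    rho: float = 1.0
    eps_abs: float = 1e-6
    eps_rel: float = 1e-4
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.eps_abs <= 0 or self.eps_rel <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass(frozen=True)
class ADMMSolution:
    """Converged (or truncated) ADMM state for one lambda."""

    x: np.ndarray
    z: np.ndarray
    u1: float
    u2: np.ndarray
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool

    @property
    def coefficients(self) -> np.ndarray:
        """The reported coefficient vector: the split copy z (exactly sparse)."""
        return self.z


@dataclass(frozen=True)
class SolutionPath:
    """Per-lambda coefficients along a decreasing regularization path."""

    lambdas: np.ndarray
    coefficients: np.ndarray  # n_lambda x p, penalized/constrained columns
    intercepts: np.ndarray  # n_lambda
    iterations: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, float)
        if lam.size > 1 and not np.all(np.diff(lam) < 0):
            raise ValueError("lambdas must be strictly decreasing")

    @property
    def n_lambdas(self) -> int:
        return int(np.asarray(self.lambdas).size)

    def gene_coefficients(self, i: int, sum_zero: bool = False) -> GeneCoefficients:
        """Coefficients at grid point i, optionally projected to sum zero."""
        values = np.array(self.coefficients[i], dtype=float)
        if sum_zero:
            values = values - values.mean()
        return GeneCoefficients(values=values, tolerance=np.inf)


class _Workspace:
    """Lambda-independent factorizations for the x-update."""

    def __init__(
        self,
        problem: ConstrainedLassoProblem,
        rho: float,
        prefer_lemma: bool | None = None,
    ):
        A, C = problem.design, problem.constraint_row
        n, m = A.shape
        self.problem = problem
        self.rho = rho
        self.Atb = A.T @ problem.response
        has_constraint = bool(np.any(C != 0.0))
        n_rows = n + 1 if has_constraint else n
        self.use_lemma = (n_rows < m) if prefer_lemma is None else prefer_lemma
        if self.use_lemma:
            if has_constraint:
                E = np.vstack([A, np.sqrt(rho) * C])
            else:
                E = A
            self.E = E
            gram = E @ E.T / rho
            gram[np.diag_indices_from(gram)] += 1.0
            self.factor = cho_factor(gram)
        else:
            M = A.T @ A
            if has_constraint:
                M = M + rho * np.outer(C, C)
            M[np.diag_indices_from(M)] += rho
            self.factor = cho_factor(M)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self.use_lemma:
            rho = self.rho
            return rhs / rho - self.E.T @ cho_solve(self.factor, self.E @ rhs) / rho**2
        return cho_solve(self.factor, rhs)


def _iterate(
    workspace: _Workspace,
    lam: float,
    config: ADMMConfig,
    warm: ADMMSolution | None,
) -> ADMMSolution:
    problem = workspace.problem
    A, C, d = problem.design, problem.constraint_row, problem.constraint_value
    pen = problem.penalize
    m = problem.m
    rho = config.rho
    thresh = lam / rho

    if warm is not None:
        z = np.array(warm.z, float)
        u1 = float(warm.u1)
        u2 = np.array(warm.u2, float)
    else:
        # Cold start at the all-zero solution with the matching scaled dual:
        # if lam >= ||A'b||_inf the KKT conditions hold at x = z = 0 with
        # u2 = A'b / rho, so this is exact there and a good guess below it.
        # Without it the dual must accumulate to ~lam/rho at rate O(1)/iter.
        z = np.zeros(m)
        u1 = 0.0
        u2 = np.where(pen, np.clip(workspace.Atb, -lam, lam) / rho, 0.0)

    Cd = C * d
    x = z
    r_norm = s_norm = np.inf
    eps_pri = eps_dual = 0.0
    converged = False
    d_norm = abs(d)
    for it in range(1, config.max_iter + 1):
        rhs = workspace.Atb + rho * (z - C * u1 + Cd - u2)
        x = workspace.solve(rhs)
        z_old = z
        v = x + u2
        z = np.where(pen, soft_threshold(v, thresh), v)
        r1 = float(C @ x - d)
        r2 = x - z
        u1 += r1
        u2 = u2 + r2
        r_norm = float(np.sqrt(r1 * r1 + r2 @ r2))
        s_norm = float(rho * np.linalg.norm(z - z_old))
        Bx_norm = float(np.sqrt((C @ x) ** 2 + x @ x))
        z_norm = float(np.linalg.norm(z))
        eps_pri = np.sqrt(m + 1) * config.eps_abs + config.eps_rel * max(
            Bx_norm, z_norm, d_norm
        )
        dual_vec_norm = float(rho * np.linalg.norm(C * u1 + u2))
        eps_dual = np.sqrt(m) * config.eps_abs + config.eps_rel * dual_vec_norm
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"ADMM did not converge in {config.max_iter} iterations "
            f"(primal {r_norm:.2e}/{eps_pri:.2e}, dual {s_norm:.2e}/{eps_dual:.2e})",
            RuntimeWarning,
            stacklevel=3,
        )
    return ADMMSolution(
        x=x,
        z=z,
        u1=u1,
        u2=u2,
        iterations=it,
        primal_residual=r_norm,
        dual_residual=s_norm,
        converged=converged,
    )


def admm_fit(
    problem: ConstrainedLassoProblem,
    lam: float,
    config: ADMMConfig | None = None,
    warm: ADMMSolution | None = None,
) -> ADMMSolution:
    """Solve the constrained lasso at a single lambda."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    config = config or ADMMConfig()
    workspace = _Workspace(problem, config.rho)
    return _iterate(workspace, lam, config, warm)


def unconstrained_fit(
    problem: ConstrainedLassoProblem,
    lam: float,
    config: ADMMConfig | None = None,
    warm: ADMMSolution | None = None,
) -> ADMMSolution:
    """Ordinary lasso on the same design: the constraint row is dropped."""
    plain = ConstrainedLassoProblem(
        design=problem.design,
        response=problem.response,
        constraint_row=np.zeros(problem.m),
        constraint_value=0.0,
        penalize=problem.penalize,
    )
    return admm_fit(plain, lam, config=config, warm=warm)


def lambda_max(problem: ConstrainedLassoProblem) -> float:
    """Smallest lambda at which all penalized coefficients are zero.

    ``||A' b||_inf`` over penalized columns, with the response centered
    first when an unpenalized intercept is present.
    """
    b = problem.response
    if problem.has_intercept:
        b = b - b.mean()
    if not np.any(np.abs(b) > 0):
        raise ValueError("response is identically zero (after intercept centering); "
                         "the regularization path is degenerate")
    corr = problem.design[:, problem.penalize].T @ b
    return float(np.max(np.abs(corr)))


def lambda_grid(lmax: float, eps_lambda: float = 0.01, count: int = 100) -> np.ndarray:
    """Geometric sequence of ``count`` values from lmax down to eps_lambda*lmax."""
    if lmax <= 0:
        raise ValueError("lmax must be positive")
    if not 0 < eps_lambda < 1:
        raise ValueError("eps_lambda must be in (0, 1)")
    if count < 2:
        raise ValueError("count must be at least 2")
    return np.geomspace(lmax, eps_lambda * lmax, count)


def solve_path(
    problem: ConstrainedLassoProblem,
    lambdas: np.ndarray,
    config: ADMMConfig | None = None,
) -> SolutionPath:
    """Warm-started fits over a decreasing lambda sequence."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or lambdas.size < 1:
        raise ValueError("lambdas must be a non-empty 1-D sequence")
    if lambdas.size > 1 and not np.all(np.diff(lambdas) < 0):
        raise ValueError("lambdas must be strictly decreasing")
    config = config or ADMMConfig()
    workspace = _Workspace(problem, config.rho)

    pen_cols = problem.penalize
    intercept_col = np.flatnonzero(~pen_cols)
    coefs = np.empty((lambdas.size, int(pen_cols.sum())))
    intercepts = np.zeros(lambdas.size)
    iters = np.empty(lambdas.size, dtype=int)
    flags = np.empty(lambdas.size, dtype=bool)
    warm: ADMMSolution | None = None
    for i, lam in enumerate(lambdas):
        warm = _iterate(workspace, float(lam), config, warm)
        coefs[i] = warm.z[pen_cols]
        if intercept_col.size:
            intercepts[i] = warm.z[intercept_col[0]]
        iters[i] = warm.iterations
        flags[i] = warm.converged
    return SolutionPath(
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=intercepts,
        iterations=iters,
        converged=flags,
    )


def build_pair_design(log_expr: np.ndarray) -> np.ndarray:
    """All pairwise log-ratio columns log x_j - log x_k, j < k, lexicographic.

    Maps an n x p matrix of log-expressions to the n x p(p-1)/2 design of
    the explicit gene-pair model.
    """
    X = np.atleast_2d(np.asarray(log_expr, dtype=float))
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least two genes to form pairs")
    jj, kk = np.triu_indices(p, k=1)
    return X[:, jj] - X[:, kk]


def l1_objective(
    design: np.ndarray,
    response: np.ndarray,
    coef: np.ndarray,
    lam: float,
    penalize: np.ndarray | None = None,
) -> float:
    """(1/2)||A x - b||^2 + lambda * sum over penalized |x_j|."""
    resid = design @ coef - response
    pen = np.abs(coef).sum() if penalize is None else np.abs(coef[penalize]).sum()
    return float(0.5 * resid @ resid + lam * pen)
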