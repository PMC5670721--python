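"""Constrained-lasso ADMM: updates, grids, paths, and oracle agreement."""

import numpy as np
import pytest

from pairzero import (
    ADMMConfig,
    ConstrainedLassoProblem,
    admm_fit,
    build_pair_design,
    l1_objective,
    lambda_grid,
    lambda_max,
    soft_threshold,
    solve_path,
    unconstrained_fit,
)
from pairzero.admm import _Workspace
from pairzero.oracle import reference_constrained_lasso, reference_lasso

TIGHT = ADMMConfig(eps_abs=1e-10, eps_rel=1e-10)


@pytest.mark.parametrize(
    "v, t, expected",
    [
        ([1.2, 0.3, -1.0], 0.5, [0.7, 0.0, -0.5]),
        ([2.0, -3.0], 0.0, [2.0, -3.0]),
        ([0.4], 0.4, [0.0]),
    ],
)
def test_soft_threshold(v, t, expected):
    np.testing.assert_allclose(soft_threshold(np.array(v), t), expected, atol=1e-15)


def test_soft_threshold_rejects_negative_threshold():
    with pytest.raises(ValueError):
        soft_threshold(np.array([1.0]), -0.1)


def test_two_gene_closed_form():
    """With A=I, b=(1,-1) and the sum-zero constraint, beta = (1-lambda, lambda-1)."""
    problem = ConstrainedLassoProblem.from_log_expression(np.eye(2), np.array([1.0, -1.0]))
    sol = admm_fit(problem, 0.4, TIGHT)
    np.testing.assert_allclose(sol.coefficients, [0.6, -0.6], atol=1e-8)


def test_all_zero_at_and_above_lambda_max(rng):
    A = rng.standard_normal((12, 6))
    b = rng.standard_normal(12)
    problem = ConstrainedLassoProblem.from_log_expression(A, b)
    lmax = lambda_max(problem)
    for lam in (lmax, 2 * lmax):
        sol = admm_fit(problem, lam, TIGHT)
        np.testing.assert_allclose(sol.coefficients, 0.0, atol=1e-9)


def test_lambda_max_formula(rng):
    one_col = ConstrainedLassoProblem.from_log_expression(
        np.array([[1.0], [1.0]]), np.array([2.0, 2.0]), constrained=False
    )
    assert lambda_max(one_col) == pytest.approx(4.0)
    with pytest.raises(ValueError, match="zero"):
        lambda_max(
            ConstrainedLassoProblem.from_log_expression(np.eye(3), np.zeros(3))
        )
    A = rng.standard_normal((5, 3))
    b = rng.standard_normal(5)
    prob = ConstrainedLassoProblem.from_log_expression(A, b)
    assert lambda_max(prob) == pytest.approx(np.max(np.abs(A.T @ b)))


def test_lambda_max_centers_response_with_intercept(rng):
    A = rng.standard_normal((8, 4))
    b = rng.standard_normal(8) + 5.0
    prob = ConstrainedLassoProblem.from_log_expression(A, b, intercept=True)
    bc = b - b.mean()
    assert lambda_max(prob) == pytest.approx(np.max(np.abs(A.T @ bc)))


def test_lambda_grid():
    np.testing.assert_allclose(lambda_grid(100.0, 0.01, 3), [100.0, 10.0, 1.0])
    np.testing.assert_allclose(lambda_grid(7.0, 0.1, 2), [7.0, 0.7])
    grid = lambda_grid(1e4, 1e-6, 100)
    assert grid.size == 100 and grid[0] == 1e4
    assert grid[-1] == pytest.approx(1e-2)
    with pytest.raises(ValueError):
        lambda_grid(1.0, 0.01, 1)
    with pytest.raises(ValueError):
        lambda_grid(-1.0, 0.01, 10)


def test_objective_matches_oracle_on_random_problems(rng):
    for p, n in [(5, 10), (10, 30), (20, 15)]:
        A = rng.standard_normal((n, p))
        b = rng.standard_normal(n)
        problem = ConstrainedLassoProblem.from_log_expression(A, b)
        sol = admm_fit(problem, 0.8, TIGHT)
        beta = sol.coefficients - sol.coefficients.mean()
        ref = reference_constrained_lasso(A, b, 0.8)
        assert l1_objective(A, b, beta, 0.8) <= l1_objective(A, b, ref, 0.8) + 1e-6


def test_factorization_branches_agree(rng):
    """Direct p x p solve and matrix-inversion-lemma solve give the same x-update."""
    A = rng.standard_normal((10, 25))  # wide: lemma branch is the default
    b = rng.standard_normal(10)
    problem = ConstrainedLassoProblem.from_log_expression(A, b)
    ws_lemma = _Workspace(problem, rho=1.0, prefer_lemma=True)
    ws_direct = _Workspace(problem, rho=1.0, prefer_lemma=False)
    assert ws_lemma.use_lemma and not ws_direct.use_lemma
    for _ in range(5):
        rhs = rng.standard_normal(25)
        np.testing.assert_allclose(ws_lemma.solve(rhs), ws_direct.solve(rhs), atol=1e-10)


def test_unconstrained_matches_sklearn(rng):
    """unconstrained_fit agrees with coordinate-descent lasso to 1e-5."""
    from sklearn.linear_model import Lasso

    n, p = 40, 8
    A = rng.standard_normal((n, p))
    b = rng.standard_normal(n)
    lam = 2.0
    problem = ConstrainedLassoProblem.from_log_expression(A, b, constrained=False)
    sol = unconstrained_fit(problem, lam, TIGHT)
    sk = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-12, max_iter=100_000).fit(A, b)
    np.testing.assert_allclose(sol.coefficients, sk.coef_, atol=1e-5)


def test_unconstrained_orthonormal_design_closed_form(rng):
    q, _ = np.linalg.qr(rng.standard_normal((20, 6)))
    b = rng.standard_normal(20)
    lam = 0.3
    problem = ConstrainedLassoProblem.from_log_expression(q, b, constrained=False)
    sol = unconstrained_fit(problem, lam, TIGHT)
    np.testing.assert_allclose(sol.coefficients, soft_threshold(q.T @ b, lam), atol=1e-8)


def test_unconstrained_objective_vs_proximal_oracle(rng):
    A = rng.standard_normal((30, 8))
    b = rng.standard_normal(30)
    problem = ConstrainedLassoProblem.from_log_expression(A, b, constrained=False)
    sol = unconstrained_fit(problem, 1.0, TIGHT)
    ref = reference_lasso(A, b, 1.0)
    gap = l1_objective(A, b, sol.coefficients, 1.0) - l1_objective(A, b, ref, 1.0)
    assert gap <= 1e-6


def test_path_warm_starts_and_determinism(rng):
    A = rng.standard_normal((30, 10))
    b = rng.standard_normal(30)
    problem = ConstrainedLassoProblem.from_log_expression(A, b)
    grid = lambda_grid(lambda_max(problem), 0.01, 20)
    path1 = solve_path(problem, grid, TIGHT)
    path2 = solve_path(problem, grid, TIGHT)
    # deterministic algorithm: identical runs are bit-for-bit identical
    assert np.array_equal(path1.coefficients, path2.coefficients)
    # at lambda_max nothing is selected
    np.testing.assert_allclose(path1.coefficients[0], 0.0, atol=1e-9)
    # training fit quality improves monotonically as lambda decreases
    train_mse = np.mean(
        (path1.coefficients @ A.T - b[None, :]) ** 2, axis=1
    )
    assert np.all(np.diff(train_mse) <= 1e-10)
    with pytest.raises(ValueError, match="decreasing"):
        solve_path(problem, grid[::-1], TIGHT)


def test_path_constraint_feasible_at_every_lambda(rng):
    A = rng.standard_normal((25, 12))
    b = rng.standard_normal(25)
    problem = ConstrainedLassoProblem.from_log_expression(A, b)
    path = solve_path(problem, lambda_grid(lambda_max(problem), 0.01, 30), TIGHT)
    sums = path.coefficients.sum(axis=1)
    assert np.all(np.abs(sums) <= 1e-8)
    assert np.all(path.converged)


@pytest.mark.parametrize(
    "log_row, expected",
    [((0.0, 1.0, 3.0), (-1.0, -3.0, -2.0))],
)
def test_build_pair_design_values(log_row, expected):
    Z = build_pair_design(np.array([log_row]))
    np.testing.assert_allclose(Z[0], expected)


def test_build_pair_design_shapes():
    assert build_pair_design(np.zeros((3, 2))).shape == (3, 1)
    assert build_pair_design(np.zeros((4, 5))).shape == (4, 10)
    with pytest.raises(ValueError):
        build_pair_design(np.zeros((3, 1)))


def test_nonconvergence_is_flagged_and_warned(rng):
    A = rng.standard_normal((20, 10))
    b = rng.standard_normal(20)
    problem = ConstrainedLassoProblem.from_log_expression(A, b)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        sol = admm_fit(problem, 0.5, ADMMConfig(eps_abs=1e-12, eps_rel=1e-12, max_iter=3))
    assert not sol.converged


def test_intercept_is_unpenalized_and_unconstrained(rng):
    A = rng.standard_normal((50, 5))
    beta = np.array([1.0, -1.0, 0.0, 0.0, 0.0])
    b = A @ beta + 3.0  # large offset absorbed by the intercept
    problem = ConstrainedLassoProblem.from_log_expression(A, b, intercept=True)
    sol = admm_fit(problem, 1e-6, TIGHT)
    assert sol.coefficients[0] == pytest.approx(3.0, abs=1e-3)
    assert abs(sol.coefficients[1:].sum()) <= 1e-8
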