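"""Metrics and benchmark protocols for the constrained gene-pair model.

Two benchmarks:

* ``convergence_benchmark`` — solver correctness at a fixed lambda: for each
  replicate an AR(1) design with a dense centered-normal beta is generated,
  the ADMM solver is run at high precision, and its solution is compared
  against an independent high-precision proximal-gradient reference.  A
  replicate succeeds when the solution satisfies the sum-to-zero constraint
  within 1e-8 and both the solution and its objective value are within 1e-8
  of the reference.  Reported as a percentage.

* ``accuracy_benchmark`` — statistical accuracy of three estimators on the
  fixed-alpha settings: the proposed constrained lasso on log-expressions,
  an ordinary lasso on the explicit pairwise log-ratio design ("lasso_pairs"),
  and an ordinary lasso on log-expressions without the constraint
  ("lasso_genes").  Per replicate, lambda is selected on an independent
  1000-point test set by MSE; MSE and R^2 are then measured on an
  independent 1000-point validation set whose predictors receive random
  N(0,1) sample-wise shifts (emulating a change of normalization), and the
  coefficient estimates are scored by relative error (RE) and false
  identification rate (FR) against the generating truth — on the pair scale
  for the pair-design lasso, on the gene scale for the other two.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .admm import (
    ADMMConfig,
    ConstrainedLassoProblem,
    build_pair_design,
    l1_objective,
    lambda_grid,
    solve_path,
    admm_fit,
)
from .oracle import reference_constrained_lasso
from .synthetic_data import (
    SimulationSetting,
    apply_sample_shifts,
    generate_dataset,
    generate_random_beta_dataset,
)

__all__ = [
    "SuccessCriteria",
    "MetricsReport",
    "ConvergenceResult",
    "mse",
    "r2",
    "relative_error",
    "false_rate",
    "convergence_benchmark",
    "accuracy_benchmark",
    "default_benchmark_grid",
]


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared residual."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.mean((y - yhat) ** 2))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Proportion of response variance explained: 1 - MSE / var(y)."""
    return 1.0 - mse(y, yhat) / float(np.var(np.asarray(y, float)))


def relative_error(estimate: np.ndarray, truth: np.ndarray) -> float:
    """||estimate - truth||_2 / ||truth||_2 (scale-free; 0 iff exact)."""
    estimate = np.asarray(estimate, float).ravel()
    truth = np.asarray(truth, float).ravel()
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have equal length")
    denom = float(np.linalg.norm(truth))
    if denom == 0:
        raise ValueError("truth vector is identically zero")
    return float(np.linalg.norm(estimate - truth)) / denom


def false_rate(
    estimate: np.ndarray, truth: np.ndarray, tol: float = 1e-10
) -> float:
    """False identification rate of the true support.

    The estimate is truncated to its |S| largest-magnitude entries, where S
    is the true support; FR = 1 - |overlap| / |S|.  Magnitude ties are
    broken by lowest index.  Invariant to positive rescaling of the
    estimate.
    """
    estimate = np.asarray(estimate, float).ravel()
    truth = np.asarray(truth, float).ravel()
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have equal length")
    support = np.flatnonzero(np.abs(truth) > tol)
    if support.size == 0:
        raise ValueError("true support is empty")
    order = np.argsort(-np.abs(estimate), kind="stable")
    top = {int(j) for j in order[: support.size] if abs(estimate[j]) > tol}
    overlap = sum(1 for j in support if int(j) in top)
    return 1.0 - overlap / support.size


@dataclass(frozen=True)
class SuccessCriteria:
    """Tolerances defining solver success in the convergence benchmark."""

    constraint_tol: float = 1e-8
    solution_tol: float = 1e-8
    solver_precision: float = 1e-10

    def __post_init__(self) -> None:
        if min(self.constraint_tol, self.solution_tol, self.solver_precision) <= 0:
            raise ValueError("all tolerances must be positive")


@dataclass(frozen=True)
class ConvergenceResult:
    """Success rate (percent) and timing of the convergence benchmark."""

    p: int
    n: int
    lam: float
    n_replicates: int
    success_rate: float
    mean_time_s: float
    failures: tuple[int, ...] = ()


def convergence_benchmark(
    p: int,
    n: int,
    n_replicates: int = 20,
    lam: float = 1.0,
    criteria: SuccessCriteria | None = None,
    base_seed: int = 0,
) -> ConvergenceResult:
    """Success rate of the ADMM solver against the independent reference.

    Per replicate (seeded ``base_seed + i``): an AR(1) design with a dense
    centered N(0,1) beta and N(0,1) noise; ADMM at ``solver_precision``
    absolute and relative tolerance; the reference optimum from the
    independent proximal-gradient solver run an order of magnitude tighter.
    Wall-clock time covers the ADMM solve only (informational).
    """
    criteria = criteria or SuccessCriteria()
    # "solver precision" means the primal/dual residual norms themselves:
    # divide out the sqrt(p+1) scaling of the absolute term and make the
    # relative term negligible, so the iteration stops at ||r||, ||s|| of
    # order solver_precision regardless of problem size
    config = ADMMConfig(
        eps_abs=criteria.solver_precision / np.sqrt(p + 1),
        eps_rel=1e-15,
    )
    successes = 0
    failures: list[int] = []
    times: list[float] = []
    for i in range(n_replicates):
        ds = generate_random_beta_dataset(p=p, n=n, seed=base_seed + i)
        problem = ConstrainedLassoProblem.from_log_expression(
            ds.log_expr, ds.response, intercept=False
        )
        t0 = time.perf_counter()
        sol = admm_fit(problem, lam, config=config)
        times.append(time.perf_counter() - t0)
        raw = sol.coefficients
        # feasibility is judged on the raw solver output; the reported beta
        # is its exact sum-zero projection (the solver's output contract,
        # and what downstream peeling consumes)
        beta_hat = raw - raw.mean()
        beta_ref = reference_constrained_lasso(ds.log_expr, ds.response, lam)
        obj_hat = l1_objective(ds.log_expr, ds.response, beta_hat, lam)
        obj_ref = l1_objective(ds.log_expr, ds.response, beta_ref, lam)
        ok = (
            sol.converged
            and abs(raw.sum()) <= criteria.constraint_tol
            and np.linalg.norm(beta_hat - beta_ref) <= criteria.solution_tol
            and abs(obj_hat - obj_ref) <= criteria.solution_tol
        )
        if ok:
            successes += 1
        else:
            failures.append(base_seed + i)
    return ConvergenceResult(
        p=p,
        n=n,
        lam=lam,
        n_replicates=n_replicates,
        success_rate=100.0 * successes / n_replicates,
        mean_time_s=float(np.mean(times)),
        failures=tuple(failures),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Replicate means and standard errors of MSE, R^2, RE and FR."""

    mse: float
    r2: float
    re: float
    fr: float
    se_mse: float
    se_r2: float
    se_re: float
    se_fr: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.fr <= 1.0:
            raise ValueError("FR must lie in [0, 1]")
        if self.re < 0:
            raise ValueError("RE must be non-negative")


def default_benchmark_grid() -> np.ndarray:
    """The fixed tuning grid: 100 log-spaced lambdas from 1e4 down to 1e-2."""
    return lambda_grid(1e4, eps_lambda=1e-6, count=100)


def _select_by_test_mse(
    predictions: np.ndarray, y_test: np.ndarray
) -> tuple[int, float]:
    errs = np.mean((predictions - y_test[None, :]) ** 2, axis=1)
    best = int(np.argmin(errs))
    return best, float(errs[best])


def _lasso_path_coefficients(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray, tol: float = 1e-7
) -> np.ndarray:
    """Unconstrained lasso path via coordinate descent (scikit-learn).

    The objective here is (1/2)||y - Xw||^2 + lam ||w||_1, i.e. sklearn's
    per-sample-scaled alpha equals lam / n.
    """
    from sklearn.linear_model import lasso_path

    n = y.size
    _, coefs, _ = lasso_path(
        X, y, alphas=np.asarray(grid, float) / n, tol=tol, max_iter=100_000
    )
    return coefs.T  # n_lambda x n_features


def _fit_select_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    truth: np.ndarray,
    constrained: bool,
    grid: np.ndarray,
    config: ADMMConfig,
) -> tuple[dict[str, float], bool]:
    if constrained:
        problem = ConstrainedLassoProblem.from_log_expression(
            X_train, y_train, intercept=False, constrained=True
        )
        path = solve_path(problem, grid, config=config)
        coef_grid = path.coefficients
        ok = bool(np.all(path.converged))
    else:
        coef_grid = _lasso_path_coefficients(X_train, y_train, grid)
        ok = True
    preds_test = coef_grid @ X_test.T
    best, _ = _select_by_test_mse(preds_test, y_test)
    coef = coef_grid[best]
    yhat_val = X_val @ coef
    out = {
        "mse": mse(y_val, yhat_val),
        "r2": r2(y_val, yhat_val),
        "re": relative_error(coef, truth),
        "fr": false_rate(coef, truth),
    }
    return out, ok


def accuracy_benchmark(
    setting_id: int,
    p: int,
    n: int,
    sigma: float,
    n_replicates: int = 20,
    base_seed: int = 0,
    grid: np.ndarray | None = None,
    config: ADMMConfig | None = None,
    n_eval: int = 1000,
) -> dict[str, MetricsReport]:
    """Accuracy comparison of the constrained fit against two lasso baselines.

    Returns a report per method: ``proposed`` (sum-to-zero constrained,
    scored against the true beta), ``lasso_pairs`` (pair-ratio design,
    scored against the true alpha), ``lasso_genes`` (unconstrained gene
    design, scored against the true beta).  Replicates where any path fit
    failed to converge are excluded (with a warning).
    """
    grid = default_benchmark_grid() if grid is None else np.asarray(grid, float)
    config = config or ADMMConfig()
    methods = ("proposed", "lasso_pairs", "lasso_genes")
    rows: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    n_excluded = 0
    for i in range(n_replicates):
        seeds = np.random.SeedSequence(base_seed + i).generate_state(4) % (2**31)
        setting = SimulationSetting(
            setting_id=setting_id, p=p, n=n, sigma=sigma, seed=int(seeds[0])
        )
        train = generate_dataset(setting, n, seed=int(seeds[0]))
        test = generate_dataset(setting, n_eval, seed=int(seeds[1]))
        val = generate_dataset(setting, n_eval, seed=int(seeds[2]))
        X_val_shifted, _ = apply_sample_shifts(val.log_expr, seed=int(seeds[3]))

        beta0 = train.true_beta.values
        alpha0 = train.true_alpha.to_dense()

        replicate: dict[str, dict[str, float]] = {}
        all_ok = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for name, constrained, pair_design in (
                ("proposed", True, False),
                ("lasso_pairs", False, True),
                ("lasso_genes", False, False),
            ):
                if pair_design:
                    tr, te, va = (
                        build_pair_design(train.log_expr),
                        build_pair_design(test.log_expr),
                        build_pair_design(X_val_shifted),
                    )
                    truth = alpha0
                else:
                    tr, te, va = train.log_expr, test.log_expr, X_val_shifted
                    truth = beta0
                metrics, ok = _fit_select_evaluate(
                    tr, train.response, te, test.response, va, val.response,
                    truth, constrained, grid, config,
                )
                replicate[name] = metrics
                all_ok = all_ok and ok
        if not all_ok:
            n_excluded += 1
            continue
        for name in methods:
            rows[name].append(replicate[name])
    if n_excluded:
        warnings.warn(
            f"{n_excluded}/{n_replicates} replicates excluded for non-convergence",
            RuntimeWarning,
        )
    if not rows["proposed"]:
        raise RuntimeError("all replicates failed to converge")

    reports: dict[str, MetricsReport] = {}
    for name in methods:
        arr = {k: np.array([r[k] for r in rows[name]]) for k in ("mse", "r2", "re", "fr")}
        k = len(rows[name])
        reports[name] = MetricsReport(
            mse=float(arr["mse"].mean()),
            r2=float(arr["r2"].mean()),
            re=float(arr["re"].mean()),
            fr=float(arr["fr"].mean()),
            se_mse=float(arr["mse"].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
            se_r2=float(arr["r2"].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
            se_re=float(arr["re"].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
            se_fr=float(arr["fr"].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
            n_replicates=k,
        )
    return reports
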