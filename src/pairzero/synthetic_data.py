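"""Synthetic gene-expression generators for the benchmark experiments.

Log-expressions are drawn iid across samples from N(0, V) with the AR(1)
covariance V_ij = rho^|i-j| (rho = 0.5), emulating locally correlated genes;
the response follows the sum-to-zero linear model on log-expressions with
iid N(0, sigma^2) noise.  Three fixed sparse pair-coefficient settings probe
the minimum-L1 conditions:

    setting 1: alpha_12=1, alpha_13=0.5, alpha_24=0.5   (not minimum-L1)
    setting 2: alpha_12=1, alpha_13=0.5, alpha_24=-0.5  (minimum, not unique)
    setting 3: alpha_12=1, alpha_13=0.5, alpha_14=0.5   (unique minimum, star)

A fourth generator draws a dense centered N(0,1) beta for solver-convergence
benchmarks.  Sample-wise shifts and positive gene/sample scalings emulate
normalization changes for the robustness experiments.

What this emulates — and does not: marginal log-normality with banded
correlation and an exactly linear log-scale signal.  Real RNA-Seq adds
count noise, zeros, and library-size artifacts that are out of scope here.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model_core import GeneCoefficients, PairCoefficients, beta_from_alpha
from .peeling import peel

__all__ = [
    "SETTING_ALPHAS",
    "SimulationSetting",
    "GeneratedDataset",
    "setting_alpha",
    "ar1_covariance",
    "generate_dataset",
    "generate_random_beta_dataset",
    "apply_sample_shifts",
    "apply_random_scaling",
]

#: The three fixed pair-coefficient settings (0-based gene indices).
SETTING_ALPHAS: dict[int, dict[tuple[int, int], float]] = {
    1: {(0, 1): 1.0, (0, 2): 0.5, (1, 3): 0.5},
    2: {(0, 1): 1.0, (0, 2): 0.5, (1, 3): -0.5},
    3: {(0, 1): 1.0, (0, 2): 0.5, (0, 3): 0.5},
}

#: Induced gene coefficients (first four genes; the rest are zero),
#: asserted at construction time.
_SETTING_BETAS: dict[int, tuple[float, float, float, float]] = {
    1: (1.5, -0.5, -0.5, -0.5),
    2: (1.5, -1.5, -0.5, 0.5),
    3: (2.0, -1.0, -0.5, -0.5),
}


def setting_alpha(setting_id: int, p: int) -> PairCoefficients:
    """The fixed pair coefficients of one of the three benchmark settings."""
    if setting_id not in SETTING_ALPHAS:
        raise ValueError(f"setting_id must be 1, 2 or 3, got {setting_id}")
    if p < 4:
        raise ValueError("the benchmark settings require p >= 4")
    alpha = PairCoefficients(p=p, entries=SETTING_ALPHAS[setting_id])
    beta = beta_from_alpha(alpha).values
    expected = np.zeros(p)
    expected[:4] = _SETTING_BETAS[setting_id]
    if not np.allclose(beta, expected, atol=1e-12):
        raise AssertionError(f"setting {setting_id} induced an unexpected beta")
    return alpha


@dataclass(frozen=True)
class SimulationSetting:
    """Configuration of one simulated experiment."""

    setting_id: Literal[1, 2, 3, "custom"]
    p: int
    n: int
    sigma: float
    ar_rho: float = 0.5
    alpha: PairCoefficients | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.ar_rho < 1:
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.setting_id in (1, 2, 3):
            if self.p < 4:
                raise ValueError("settings 1-3 require p >= 4")
            object.__setattr__(self, "alpha", setting_alpha(self.setting_id, self.p))
        elif self.alpha is None:
            raise ValueError("a custom setting must provide alpha")


@dataclass(frozen=True)
class GeneratedDataset:
    """Simulated log-expressions, response, and the generating truth."""

    log_expr: np.ndarray
    response: np.ndarray
    true_alpha: PairCoefficients
    true_beta: GeneCoefficients
    seed: int


def ar1_covariance(p: int, rho: float = 0.5) -> np.ndarray:
    """AR(1) covariance V_ij = rho^|i-j| (symmetric positive definite)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _draw_log_expr(
    rng: np.random.Generator, n: int, p: int, ar_rho: float
) -> np.ndarray:
    chol = np.linalg.cholesky(ar1_covariance(p, ar_rho))
    return rng.standard_normal((n, p)) @ chol.T


def generate_dataset(
    setting: SimulationSetting, n_points: int, seed: int | None = None
) -> GeneratedDataset:
    """Draw one dataset from a fixed-alpha setting.

    ``seed`` overrides ``setting.seed`` (used for independent train/test/
    validation draws from the same setting).
    """
    if n_points < 1:
        raise ValueError("n_points must be positive")
    use_seed = setting.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    X = _draw_log_expr(rng, n_points, setting.p, setting.ar_rho)
    beta = beta_from_alpha(setting.alpha)
    y = X @ beta.values + setting.sigma * rng.standard_normal(n_points)
    return GeneratedDataset(
        log_expr=X,
        response=y,
        true_alpha=setting.alpha,
        true_beta=beta,
        seed=use_seed,
    )


def generate_random_beta_dataset(
    p: int,
    n: int,
    seed: int,
    sigma: float = 1.0,
    ar_rho: float = 0.5,
) -> GeneratedDataset:
    """Dataset with a dense random sum-to-zero beta (solver benchmarks).

    beta is drawn iid N(0,1) and centered to sum exactly to zero; noise is
    N(0, sigma^2) with sigma = 1; the design is the same AR(1) log-normal
    ensemble.  The matching minimum-L1 pair truth is obtained by peeling.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(p)
    beta = GeneCoefficients(values=raw - raw.mean(), tolerance=1e-12)
    X = _draw_log_expr(rng, n, p, ar_rho)
    y = X @ beta.values + sigma * rng.standard_normal(n)
    alpha, _ = peel(beta)
    return GeneratedDataset(
        log_expr=X, response=y, true_alpha=alpha, true_beta=beta, seed=seed
    )


def apply_sample_shifts(
    log_expr: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Add an iid N(0,1) constant to every gene of each sample (row).

    In raw-expression space this is a random per-sample rescaling; models
    whose coefficients sum to zero predict identically before and after.
    Returns the shifted matrix and the shifts.
    """
    X = np.atleast_2d(np.asarray(log_expr, dtype=float))
    rng = np.random.default_rng(seed)
    shifts = rng.standard_normal(X.shape[0])
    return X + shifts[:, None], shifts


def apply_random_scaling(
    expression: np.ndarray,
    per_gene: bool = False,
    per_sample: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiply a positive expression matrix by random positive factors.

    Factors are log-normal(0,1), drawn per sample (row) and/or per gene
    (column); any positive law would do for the invariance being probed.
    Returns (scaled, sample_factors, gene_factors); factors are ones when
    the corresponding flag is off.
    """
    X = np.atleast_2d(np.asarray(expression, dtype=float))
    if np.any(X <= 0):
        raise ValueError("expression must be strictly positive to be scaled and logged")
    rng = np.random.default_rng(seed)
    sample_factors = np.exp(rng.standard_normal(X.shape[0])) if per_sample else np.ones(X.shape[0])
    gene_factors = np.exp(rng.standard_normal(X.shape[1])) if per_gene else np.ones(X.shape[1])
    scaled = X * sample_factors[:, None] * gene_factors[None, :]
    return scaled, sample_factors, gene_factors
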