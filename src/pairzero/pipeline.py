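"""End-to-end RNA-Seq screening and gene-pair fitting pipeline.

Input is a genes x samples matrix of non-negative normalized expression
estimates (e.g. RSEM) as delimited text, plus a positive continuous
per-sample response (e.g. pre-operative PSA).  The pipeline

1. drops genes whose mean normalized expression is below a cutoff
   (default 10);
2. screens the survivors by the Pearson correlation between log-expression
   and log-response, keeping genes whose Benjamini-Hochberg FDR is at most
   a cutoff (default 0.01);
3. fits the sum-to-zero constrained lasso path on the retained
   log-expressions (with an unpenalized intercept), and
4. peels each point of the path into its minimum-L1 gene-pair
   representation, reporting genes in the order they first enter the path.

Because the fitted coefficients sum to zero, the whole procedure is
invariant to per-sample rescaling of the raw expressions, and (through the
intercept) to per-gene rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .admm import (
    ADMMConfig,
    ConstrainedLassoProblem,
    SolutionPath,
    lambda_grid,
    lambda_max,
    solve_path,
)
from .model_core import DEFAULT_NONZERO_TOL, PairCoefficients
from .peeling import peel

__all__ = [
    "ExpressionMatrix",
    "ScreeningReport",
    "PipelineResult",
    "read_expression",
    "write_expression",
    "filter_low_expression",
    "bh_adjust",
    "pearson_screen",
    "fit_pipeline",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples non-negative expression values with identifiers."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("expression values must be finite and non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            values=self.values[keep],
            gene_ids=tuple(np.asarray(self.gene_ids)[keep]),
            sample_ids=self.sample_ids,
        )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {path}: {dupes[:5]}")
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values) | (values < 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"invalid expression value at gene {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r} (line {r + 2} of {path})"
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(map(str, frame.index)),
        sample_ids=tuple(map(str, frame.columns)),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x samples TSV round-trippable by :func:`read_expression`."""
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)
    )
    frame.index.name = "gene"
    # shortest-repr floats + round_trip parsing make write -> read lossless
    frame.to_csv(path, sep="\t")


def filter_low_expression(
    matrix: ExpressionMatrix, min_mean: float = 10.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose mean expression is strictly below ``min_mean``."""
    means = matrix.values.mean(axis=1)
    keep = means >= min_mean
    if not np.any(keep):
        raise ValueError(f"all genes fall below the mean-expression cutoff {min_mean}")
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    return matrix.subset(keep), dropped


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p_values = np.asarray(p_values, dtype=float).ravel()
    if p_values.size == 0:
        return p_values
    if np.any((p_values < 0) | (p_values > 1) | ~np.isfinite(p_values)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


@dataclass(frozen=True)
class ScreeningReport:
    """Per-gene screening statistics and the retention decision."""

    gene_ids: tuple[str, ...]
    mean_expression: np.ndarray
    pearson_r: np.ndarray  # NaN where undefined (constant gene)
    p_value: np.ndarray
    fdr: np.ndarray
    retained: np.ndarray
    excluded_reasons: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.gene_ids),
                "mean_expression": self.mean_expression,
                "pearson_r": self.pearson_r,
                "p_value": self.p_value,
                "fdr": self.fdr,
                "retained": self.retained,
            }
        )


def pearson_screen(
    matrix: ExpressionMatrix,
    response: np.ndarray,
    fdr_cutoff: float = 0.01,
    pseudocount: float | None = None,
) -> ScreeningReport:
    """Screen genes by Pearson correlation of log-expression vs log-response.

    Two-sided p-values come from the exact t transform with n - 2 degrees
    of freedom; the Benjamini-Hochberg adjustment runs across all testable
    genes, and a gene is retained iff its FDR is at most ``fdr_cutoff``.
    Constant genes have no defined correlation and are excluded with a
    recorded reason.  Zeros in the expression are an error unless a
    ``pseudocount`` (added before the log) is supplied.
    """
    y = np.asarray(response, dtype=float).ravel()
    if y.size != matrix.n_samples:
        raise ValueError("response length must equal the number of samples")
    if y.size < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive (it is log-transformed)")
    values = matrix.values
    if pseudocount is not None:
        values = values + pseudocount
    if np.any(values <= 0):
        raise ValueError(
            "expression contains zeros; pass a pseudocount to enable the log transform"
        )
    log_x = np.log(values)
    log_y = np.log(y)

    n = y.size
    xc = log_x - log_x.mean(axis=1, keepdims=True)
    yc = log_y - log_y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = float(np.sqrt((yc**2).sum()))
    # exact range catches constant genes that centering leaves with rounding dust
    constant = np.ptp(log_x, axis=1) == 0
    sx[constant] = np.nan
    r = np.full(matrix.n_genes, np.nan)
    ok = ~constant
    r[ok] = (xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)

    p = np.full(matrix.n_genes, np.nan)
    with np.errstate(divide="ignore"):
        t = r[ok] * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 1e-300))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    fdr = np.full(matrix.n_genes, np.nan)
    if np.any(ok):
        fdr[ok] = bh_adjust(p[ok])
    retained = np.zeros(matrix.n_genes, dtype=bool)
    retained[ok] = fdr[ok] <= fdr_cutoff
    reasons = {
        matrix.gene_ids[i]: "constant log-expression"
        for i in np.flatnonzero(constant)
    }
    return ScreeningReport(
        gene_ids=matrix.gene_ids,
        mean_expression=values.mean(axis=1),
        pearson_r=r,
        p_value=p,
        fdr=fdr,
        retained=retained,
        excluded_reasons=reasons,
    )


@dataclass(frozen=True)
class PipelineResult:
    """Constrained path, peeled pairs per lambda, and the entry report."""

    gene_ids: tuple[str, ...]
    path: SolutionPath
    pairs: tuple[PairCoefficients, ...]
    entry_order: tuple[str, ...]
    nonzero_tol: float

    @property
    def first_pair(self) -> tuple[str, str] | None:
        """The heaviest pair at the first lambda where any pair is active."""
        for alpha in self.pairs:
            if len(alpha):
                (j, k), _ = max(alpha.entries.items(), key=lambda it: abs(it[1]))
                return self.gene_ids[j], self.gene_ids[k]
        return None

    def pairs_frame(self, i: int) -> pd.DataFrame:
        """Pair table (gene_j, gene_k, alpha) at grid point i."""
        rows = [
            (self.gene_ids[j], self.gene_ids[k], v)
            for (j, k), v in self.pairs[i]
        ]
        return pd.DataFrame(rows, columns=["gene_j", "gene_k", "alpha"])


def fit_pipeline(
    matrix: ExpressionMatrix,
    response: np.ndarray,
    config: ADMMConfig | None = None,
    lambdas: np.ndarray | None = None,
    intercept: bool = True,
    pseudocount: float | None = None,
    nonzero_tol: float | None = None,
) -> PipelineResult:
    """Fit the constrained path on log-expressions and peel it into pairs.

    ``matrix`` is the (already screened) genes x samples expression;
    internally the design is samples x genes log-expression.  Each lambda's
    coefficient vector is restricted to its active support and projected
    exactly onto the sum-to-zero hyperplane before peeling, so the peeling
    precondition holds without smearing rounding dust over inactive genes.
    The entry order records genes by the first (largest) lambda at which
    their coefficient magnitude exceeds ``nonzero_tol``; the default sits
    two orders of magnitude above the solver's absolute tolerance so that
    entry decisions are reproducible across numerically equivalent runs
    (e.g. before and after per-sample rescaling).
    """
    y = np.asarray(response, dtype=float).ravel()
    if y.size != matrix.n_samples:
        raise ValueError("response length must equal the number of samples")
    values = matrix.values
    if pseudocount is not None:
        values = values + pseudocount
    if np.any(values <= 0):
        raise ValueError(
            "expression contains zeros; pass a pseudocount to enable the log transform"
        )
    config = config or ADMMConfig()
    if nonzero_tol is None:
        nonzero_tol = max(DEFAULT_NONZERO_TOL, 100.0 * config.eps_abs)
    X = np.log(values).T  # samples x genes
    problem = ConstrainedLassoProblem.from_log_expression(X, y, intercept=intercept)
    if lambdas is None:
        # the default grid anchor is computed on the row-centered design:
        # feasible (sum-zero) coefficients cannot see a per-sample constant,
        # so this lambda_max still forces the all-zero solution while being
        # invariant to per-sample rescaling of the raw expressions
        probe = ConstrainedLassoProblem.from_log_expression(
            X - X.mean(axis=1, keepdims=True), y, intercept=intercept
        )
        lambdas = lambda_grid(lambda_max(probe))
    path = solve_path(problem, lambdas, config=config)

    pairs = []
    for i in range(path.n_lambdas):
        raw = path.coefficients[i]
        mask = np.abs(raw) > nonzero_tol
        vals = np.where(mask, raw, 0.0)
        if mask.any():
            vals[mask] -= vals[mask].mean()  # re-balance on the support only
        alpha, _ = peel(vals)
        pairs.append(alpha)

    entry_idx: dict[int, int] = {}
    for i in range(path.n_lambdas):
        active = np.flatnonzero(np.abs(path.coefficients[i]) > nonzero_tol)
        for g in active:
            entry_idx.setdefault(int(g), i)
    ordered = sorted(entry_idx, key=lambda g: (entry_idx[g], g))
    entry_order = tuple(matrix.gene_ids[g] for g in ordered)
    return PipelineResult(
        gene_ids=matrix.gene_ids,
        path=path,
        pairs=tuple(pairs),
        entry_order=entry_order,
        nonzero_tol=nonzero_tol,
    )
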