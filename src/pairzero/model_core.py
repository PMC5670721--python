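"""Correspondence between gene-pair coefficients and sum-to-zero gene coefficients.

A linear model on all pairwise log-expression ratios,

    y = sum_{j<k} alpha_jk * (log x_j - log x_k) + eps,

is equivalent to a model on the individual log-expressions,

    y = sum_j beta_j * log x_j + eps,    with  sum_j beta_j = 0,

where ``beta_j = sum_{k != j} alpha_jk`` under the antisymmetric convention
``alpha_kj = -alpha_jk``.  The map alpha -> beta is many-to-one: adding a
constant around any cycle of pair indices leaves beta unchanged.  Among all
pair representations of a given beta we single out those of minimum L1 norm;
this module provides the beta_from_alpha map and checkable characterizations
of minimum-L1 and uniquely-minimum-L1 representations, together with support
count relations between the two parameterizations.

Indices are 0-based internally; reports and file formats use gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

#: Magnitude below which a fitted coefficient is treated as zero.  Fitted
#: coefficients are floating point, so "nonzero" needs a cutoff; 1e-10 sits
#: well below solver precision and well above accumulated rounding error.
DEFAULT_NONZERO_TOL = 1e-10

__all__ = [
    "DEFAULT_NONZERO_TOL",
    "PairCoefficients",
    "GeneCoefficients",
    "DecompositionReport",
    "beta_from_alpha",
    "is_minimum_l1",
    "is_unique_minimum_l1",
    "support_counts",
]


@dataclass(frozen=True)
class PairCoefficients:
    """Sparse antisymmetric pair-indexed coefficients alpha.

    Parameters
    ----------
    p
        Number of genes.
    entries
        Mapping from an ordered index pair ``(j, k)`` with ``0 <= j < k < p``
        to the coefficient ``alpha_jk``.  Only the upper triangle is stored;
        ``alpha_kj = -alpha_jk`` by convention.  Exact-zero entries are
        pruned at construction (sparse canonical form).
    """

    p: int
    entries: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        clean: dict[tuple[int, int], float] = {}
        for (j, k), value in dict(self.entries).items():
            j, k = int(j), int(k)
            if not (0 <= j < k < self.p):
                raise ValueError(
                    f"pair index ({j}, {k}) out of range for p={self.p}; need 0 <= j < k < p"
                )
            value = float(value)
            if not np.isfinite(value):
                raise ValueError(f"non-finite coefficient for pair ({j}, {k})")
            if value != 0.0:
                clean[(j, k)] = value
        object.__setattr__(self, "entries", clean)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(sorted(self.entries.items()))

    @property
    def l1(self) -> float:
        """L1 norm over stored (upper-triangle) entries."""
        return float(sum(abs(v) for v in self.entries.values()))

    def to_dense(self) -> np.ndarray:
        """Length-q vector, q = p(p-1)/2, in lexicographic pair order."""
        q = self.p * (self.p - 1) // 2
        out = np.zeros(q)
        for (j, k), value in self.entries.items():
            out[_pair_rank(j, k, self.p)] = value
        return out

    @classmethod
    def from_dense(
        cls, values: np.ndarray, p: int, tol: float = DEFAULT_NONZERO_TOL
    ) -> "PairCoefficients":
        """Build from a length-q lexicographic vector, pruning |v| <= tol."""
        values = np.asarray(values, dtype=float)
        q = p * (p - 1) // 2
        if values.shape != (q,):
            raise ValueError(f"expected shape ({q},) for p={p}, got {values.shape}")
        jj, kk = np.triu_indices(p, k=1)
        entries = {
            (int(j), int(k)): float(v)
            for j, k, v in zip(jj, kk, values)
            if abs(v) > tol
        }
        return cls(p=p, entries=entries)


def _pair_rank(j: int, k: int, p: int) -> int:
    # lexicographic position of (j,k), j<k, among the p(p-1)/2 ordered pairs
    return j * (2 * p - j - 1) // 2 + (k - j - 1)


@dataclass(frozen=True)
class GeneCoefficients:
    """Length-p coefficient vector beta constrained to sum to zero.

    ``tolerance`` bounds the admissible |sum(beta)|; the default scales with
    the L1 norm so that solver output at realistic precision validates.
    """

    values: np.ndarray
    tolerance: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("beta must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("beta contains non-finite values")
        tol = self.tolerance
        if tol is None:
            tol = 1e-8 * max(1.0, float(np.abs(values).sum()))
        elif tol < 0:
            raise ValueError("tolerance must be non-negative")
        total = float(values.sum())
        if abs(total) > tol:
            raise ValueError(
                f"beta violates the sum-to-zero constraint: sum={total:.3e} > tol={tol:.3e}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "tolerance", float(tol))

    @property
    def p(self) -> int:
        return int(self.values.size)

    @property
    def l1(self) -> float:
        return float(np.abs(self.values).sum())


@dataclass(frozen=True)
class DecompositionReport:
    """Support counts of a pair representation and its induced gene vector.

    ``n_pairs`` counts nonzero alpha entries; ``n_genes`` counts nonzero
    entries of the induced beta.  ``is_minimum`` / ``is_unique`` record the
    minimum-L1 and uniquely-minimum-L1 conditions.
    """

    n_pairs: int
    n_genes: int
    is_minimum: bool
    is_unique: bool
    l1_alpha: float
    l1_beta: float

    def __post_init__(self) -> None:
        if self.n_pairs < 0 or self.n_genes < 0:
            raise ValueError("support counts must be non-negative")
        if self.is_unique and not self.is_minimum:
            raise ValueError("a uniquely minimal representation must be minimal")


def beta_from_alpha(alpha: PairCoefficients) -> GeneCoefficients:
    """Map pair coefficients to the induced sum-to-zero gene coefficients.

    ``beta_j = sum_{k != j} alpha_jk`` with ``alpha_kj = -alpha_jk``; the
    result sums to zero exactly in exact arithmetic because every stored
    entry contributes +v to one gene and -v to the other.
    """
    beta = np.zeros(alpha.p)
    for (j, k), value in alpha.entries.items():
        beta[j] += value
        beta[k] -= value
    tol = 1e-12 * max(1.0, alpha.l1)
    return GeneCoefficients(values=beta, tolerance=tol)


def _neighbor_signs(alpha: PairCoefficients) -> dict[int, dict[int, float]]:
    """Adjacency with edge values seen from each endpoint (antisymmetric)."""
    adj: dict[int, dict[int, float]] = {}
    for (j, k), value in alpha.entries.items():
        adj.setdefault(j, {})[k] = value
        adj.setdefault(k, {})[j] = -value
    return adj


def is_minimum_l1(
    alpha: PairCoefficients, tol: float = DEFAULT_NONZERO_TOL
) -> tuple[bool, tuple[int, int, int] | None]:
    """Test whether alpha is a minimum-L1 representation of its induced beta.

    The representation is minimal iff no two coefficients sharing an index
    have a strictly positive product under the antisymmetric extension:
    ``alpha_ij * alpha_jk <= 0`` for all i != j, j != k.  Equivalently, at
    every gene j all incident coefficients ``alpha_jk`` carry the same sign.

    Returns ``(flag, witness)`` where ``witness`` is a violating 0-based
    triple ``(i, j, k)`` (meaning ``alpha_ij * alpha_jk > 0``) or None.
    Only stored nonzeros and their shared indices are scanned, O(A * deg),
    which is equivalent to the full O(p^3) scan because zero entries never
    produce a positive product.

    When the flag is true the L1 identity ``||alpha||_1 = ||beta||_1 / 2``
    must hold; it is verified defensively.
    """
    adj = _neighbor_signs(alpha)
    for j, incident in adj.items():
        pos = [k for k, v in incident.items() if v > tol]
        neg = [k for k, v in incident.items() if v < -tol]
        if pos and neg:
            # alpha_{i j} = -alpha_{j i} > 0 for i in neg, and alpha_{j k} > 0
            i = min(neg)
            k = min(pos)
            return False, (i, j, k)
    half_beta = beta_from_alpha(alpha).l1 / 2.0
    if abs(alpha.l1 - half_beta) > 1e-9 * max(1.0, alpha.l1):
        raise AssertionError(
            "minimum-L1 norm identity violated: "
            f"||alpha||_1={alpha.l1:.12g} vs ||beta||_1/2={half_beta:.12g}"
        )
    return True, None


def is_unique_minimum_l1(
    alpha: PairCoefficients, tol: float = DEFAULT_NONZERO_TOL
) -> bool:
    """Test whether alpha is the unique minimum-L1 representation.

    Uniqueness holds iff the representation is minimal and all nonzero
    entries share one common hub index (a star: no two pairs with four
    distinct indices).  On the induced beta this is equivalent to the
    existence of a hub j with ``|beta_j| = sum_{i != j} |beta_i|``.
    """
    entries = [(jk, v) for jk, v in alpha.entries.items() if abs(v) > tol]
    if not entries:
        return True  # vacuous: the zero representation is trivially unique
    minimal, _ = is_minimum_l1(alpha, tol=tol)
    if not minimal:
        return False
    (j0, k0), _ = entries[0]
    hubs = {j0, k0}
    for (j, k), _ in entries[1:]:
        hubs &= {j, k}
        if not hubs:
            return False
    return True


def support_counts(
    alpha: PairCoefficients, tol: float = DEFAULT_NONZERO_TOL
) -> DecompositionReport:
    """Count nonzero supports of alpha and its induced beta.

    The counts obey: ``n_genes <= 2 * n_pairs`` always; under the minimum-L1
    conditions additionally ``2 * sqrt(n_pairs) <= n_genes`` (the nonzero
    pattern forms a bipartite graph); under uniqueness with a nonzero alpha,
    ``n_genes = n_pairs + 1`` (a star).
    """
    beta = beta_from_alpha(alpha)
    n_pairs = sum(1 for v in alpha.entries.values() if abs(v) > tol)
    n_genes = int(np.sum(np.abs(beta.values) > tol))
    minimal, _ = is_minimum_l1(alpha, tol=tol)
    unique = is_unique_minimum_l1(alpha, tol=tol)
    return DecompositionReport(
        n_pairs=n_pairs,
        n_genes=n_genes,
        is_minimum=minimal,
        is_unique=unique,
        l1_alpha=alpha.l1,
        l1_beta=beta.l1,
    )
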