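"""Peeling: convert a sum-to-zero beta into a minimum-L1 gene-pair alpha.

Repeatedly pair the most positive remaining coefficient with the most
negative one, transfer the smaller magnitude onto that gene pair, and zero
the exhausted coefficient.  Each step removes at least one nonzero (two when
the magnitudes tie), so the algorithm terminates within p steps.  The result
always attains the minimum L1 norm ``||alpha||_1 = ||beta||_1 / 2``: every
step grows ``||alpha||_1`` by the transferred weight while shrinking the
remaining ``||beta||_1`` by twice that weight.

Different tie-breaking orders can yield different (equally minimal) pair
sets; here ties are broken by lowest index, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import GeneCoefficients, PairCoefficients

__all__ = ["PeelingTrace", "peel", "project_sum_zero"]

#: Pair weights below this are floating-point dust near termination and are
#: dropped; the round-trip contract still holds at 1e-10.
WEIGHT_DROP_TOL = 1e-12

#: Admissible |sum(beta)| relative to max(1, ||beta||_1) before peeling; any
#: residual within it is mean-projected away so the loop terminates cleanly.
SUM_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class PeelingTrace:
    """Ordered record of peeling steps: (positive index, negative index, weight)."""

    steps: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    @property
    def iterations(self) -> int:
        return len(self.steps)

    @property
    def total_transferred(self) -> float:
        """Sum of 2*weight over steps; equals ||beta||_1 up to dropped dust."""
        return float(sum(2.0 * w for _, _, w in self.steps))


def project_sum_zero(values: np.ndarray) -> GeneCoefficients:
    """Project a vector onto the sum-to-zero hyperplane by removing its mean."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("expected a non-empty 1-D vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    centered = values - values.mean()
    return GeneCoefficients(values=centered, tolerance=max(1e-12, 1e-15 * values.size))


def peel(
    beta: GeneCoefficients | np.ndarray,
    drop_tol: float = WEIGHT_DROP_TOL,
) -> tuple[PairCoefficients, PeelingTrace]:
    """Decompose beta into a minimum-L1 set of gene pairs.

    Parameters
    ----------
    beta
        Sum-to-zero coefficient vector (or raw vector whose residual sum is
        within ``SUM_ZERO_TOL * max(1, ||beta||_1)``; it is mean-projected).
    drop_tol
        Weights below this near termination are discarded as rounding dust.

    Returns
    -------
    alpha, trace
        Pair coefficients with ``beta_from_alpha(alpha) == beta`` (within
        1e-10), ``||alpha||_1 = ||beta||_1 / 2``, at most p-1 stored pairs,
        and a step-by-step trace.

    Raises
    ------
    ValueError
        If the input violates the sum-to-zero constraint beyond tolerance.
    """
    values = beta.values if isinstance(beta, GeneCoefficients) else np.asarray(beta, float)
    if values.ndim != 1:
        raise ValueError("beta must be 1-D")
    l1 = float(np.abs(values).sum())
    total = float(values.sum())
    if abs(total) > SUM_ZERO_TOL * max(1.0, l1):
        raise ValueError(
            f"input does not sum to zero: sum={total:.3e} exceeds tolerance "
            f"{SUM_ZERO_TOL * max(1.0, l1):.3e}; center the vector first"
        )
    work = values - values.mean()  # exact feasibility for clean termination
    p = work.size

    entries: dict[tuple[int, int], float] = {}
    steps: list[tuple[int, int, float]] = []
    for _ in range(p):  # terminates in <= p steps; each removes >= 1 nonzero
        k1 = int(np.argmax(work))  # most positive, lowest index on ties
        k2 = int(np.argmin(work))  # most negative, lowest index on ties
        if work[k1] <= drop_tol or -work[k2] <= drop_tol:
            break
        weight = min(work[k1], -work[k2])
        if k1 < k2:
            entries[(k1, k2)] = entries.get((k1, k2), 0.0) + weight
        else:
            entries[(k2, k1)] = entries.get((k2, k1), 0.0) - weight
        # zero the exhausted side exactly to avoid residual dust
        if work[k1] <= -work[k2]:
            work[k2] += weight
            work[k1] = 0.0
        else:
            work[k1] -= weight
            work[k2] = 0.0
        steps.append((k1, k2, float(weight)))

    alpha = PairCoefficients(p=p, entries=entries)
    return alpha, PeelingTrace(steps=tuple(steps))
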