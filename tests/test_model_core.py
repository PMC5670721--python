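"""Pair-to-gene coefficient correspondence and minimum-L1 characterizations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairzero import (
    GeneCoefficients,
    PairCoefficients,
    beta_from_alpha,
    is_minimum_l1,
    is_unique_minimum_l1,
    setting_alpha,
    support_counts,
)
from conftest import random_sparse_alpha


@pytest.mark.parametrize(
    "p, entries, expected_beta",
    [
        (3, {(0, 1): 3.0, (1, 2): -2.0}, [3.0, -5.0, 2.0]),
        (4, {}, [0.0, 0.0, 0.0, 0.0]),
        (5, {(0, 1): 1.0, (0, 2): 0.5, (0, 3): 0.5}, [2.0, -1.0, -0.5, -0.5, 0.0]),
    ],
)
def test_beta_from_alpha_worked_examples(p, entries, expected_beta):
    beta = beta_from_alpha(PairCoefficients(p=p, entries=entries))
    np.testing.assert_allclose(beta.values, expected_beta, atol=1e-15)


def test_pair_coefficients_validation():
    with pytest.raises(ValueError):
        PairCoefficients(p=3, entries={(1, 1): 1.0})  # j < k required
    with pytest.raises(ValueError):
        PairCoefficients(p=3, entries={(0, 3): 1.0})  # out of range
    # exact zeros are pruned to canonical sparse form
    a = PairCoefficients(p=4, entries={(0, 1): 0.0, (1, 2): 2.0})
    assert len(a) == 1


def test_gene_coefficients_sum_zero_enforced():
    with pytest.raises(ValueError, match="sum-to-zero"):
        GeneCoefficients(values=np.array([1.0, 1.0]), tolerance=1e-10)
    ok = GeneCoefficients(values=np.array([1.0, -1.0]))
    assert ok.p == 2 and ok.l1 == 2.0


def test_dense_round_trip(rng):
    a = random_sparse_alpha(rng, p=8, n_entries=5)
    back = PairCoefficients.from_dense(a.to_dense(), p=8)
    assert back.entries == a.entries


@pytest.mark.parametrize(
    "setting_id, minimal, unique",
    [(1, False, None), (2, True, False), (3, True, True)],
)
def test_benchmark_settings_minimality(setting_id, minimal, unique):
    alpha = setting_alpha(setting_id, p=20)
    flag, witness = is_minimum_l1(alpha)
    assert flag is minimal
    if not minimal:
        # the violating triple shares the middle index: alpha_ij * alpha_jk > 0
        i, j, k = witness
        assert (i, j, k) == (0, 1, 3)  # genes 1, 2, 4 in 1-based reporting
    else:
        assert witness is None
        assert is_unique_minimum_l1(alpha) is unique


def test_empty_alpha_is_vacuously_minimal_and_unique():
    empty = PairCoefficients(p=6, entries={})
    assert is_minimum_l1(empty) == (True, None)
    assert is_unique_minimum_l1(empty)
    rep = support_counts(empty)
    assert rep.n_pairs == 0 and rep.n_genes == 0


@pytest.mark.parametrize(
    "setting_id, n_pairs, n_genes",
    [(1, 3, 4), (2, 3, 4), (3, 3, 4)],
)
def test_support_counts_on_settings(setting_id, n_pairs, n_genes):
    rep = support_counts(setting_alpha(setting_id, p=10))
    assert rep.n_pairs == n_pairs
    assert rep.n_genes == n_genes
    if setting_id == 3:
        assert rep.is_unique and rep.n_genes == rep.n_pairs + 1
    assert rep.n_genes <= 2 * rep.n_pairs


def test_support_count_bounds_on_random_alphas(rng):
    """B <= 2A always; 2*sqrt(A) <= B when minimal; B = A+1 when unique."""
    for _ in range(1000):
        alpha = random_sparse_alpha(rng)
        rep = support_counts(alpha)
        assert rep.n_genes <= 2 * rep.n_pairs
        if rep.is_minimum:
            assert 2 * np.sqrt(rep.n_pairs) <= rep.n_genes + 1e-12
        if rep.is_unique and rep.n_pairs > 0:
            assert rep.n_genes == rep.n_pairs + 1


def test_minimum_l1_norm_identity(rng):
    """Minimal representations satisfy ||alpha||_1 = ||beta||_1 / 2, others exceed it."""
    n_minimal = 0
    for _ in range(300):
        alpha = random_sparse_alpha(rng)
        beta = beta_from_alpha(alpha)
        flag, _ = is_minimum_l1(alpha)
        if flag:
            n_minimal += 1
            assert alpha.l1 == pytest.approx(beta.l1 / 2, rel=1e-12)
        else:
            assert alpha.l1 > beta.l1 / 2 - 1e-12
    assert n_minimal > 10  # the sample covers both branches


def test_unique_minimal_hub_condition(rng):
    """Star uniqueness is equivalent to a hub with |beta_j| = sum_{i!=j} |beta_i|."""
    for _ in range(300):
        alpha = random_sparse_alpha(rng)
        beta = np.abs(beta_from_alpha(alpha).values)
        hub_exists = bool(np.any(beta >= beta.sum() - beta - 1e-12)) and beta.sum() > 0
        if is_unique_minimum_l1(alpha) and len(alpha):
            j = int(np.argmax(beta))
            assert beta[j] == pytest.approx(beta.sum() - beta[j], rel=1e-12)
        elif len(alpha) and is_minimum_l1(alpha)[0] and not is_unique_minimum_l1(alpha):
            j = int(np.argmax(beta))
            assert beta[j] < beta.sum() - beta[j] + 1e-9


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_cycle_gauge_invariance(data):
    """Adding a constant along any index cycle leaves the induced beta unchanged."""
    p = data.draw(st.integers(min_value=3, max_value=10))
    cycle_len = data.draw(st.integers(min_value=3, max_value=p))
    cycle = data.draw(
        st.permutations(range(p)).map(lambda perm: list(perm)[:cycle_len])
    )
    c = data.draw(st.floats(min_value=-5, max_value=5, allow_nan=False))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
    alpha = random_sparse_alpha(rng, p=p)
    entries = dict(alpha.entries)
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        if a < b:
            entries[(a, b)] = entries.get((a, b), 0.0) + c
        else:
            entries[(b, a)] = entries.get((b, a), 0.0) - c
    shifted = PairCoefficients(p=p, entries=entries)
    np.testing.assert_allclose(
        beta_from_alpha(shifted).values,
        beta_from_alpha(alpha).values,
        atol=1e-9,
    )


def test_induced_beta_sums_to_zero(rng):
    for _ in range(200):
        alpha = random_sparse_alpha(rng)
        beta = beta_from_alpha(alpha)
        assert abs(beta.values.sum()) <= 1e-12 * max(1.0, alpha.l1)
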