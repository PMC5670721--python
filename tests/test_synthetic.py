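"""Synthetic generators: AR(1) designs, fixed settings, shifts and scalings."""

import numpy as np
import pytest

from pairzero import (
    SimulationSetting,
    apply_random_scaling,
    apply_sample_shifts,
    ar1_covariance,
    beta_from_alpha,
    generate_dataset,
    generate_random_beta_dataset,
    setting_alpha,
)


def test_ar1_covariance_values():
    V = ar1_covariance(3, 0.5)
    np.testing.assert_allclose(np.diag(V), 1.0)
    assert V[0, 2] == pytest.approx(0.25)
    assert V[0, 1] == V[1, 0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ar1_covariance(3, 1.0)


def test_ar1_covariance_positive_definite_at_scale():
    eigs = np.linalg.eigvalsh(ar1_covariance(200, 0.5))
    assert eigs.min() > 0


@pytest.mark.parametrize(
    "setting_id, expected",
    [
        (1, [1.5, -0.5, -0.5, -0.5]),
        (2, [1.5, -1.5, -0.5, 0.5]),
        (3, [2.0, -1.0, -0.5, -0.5]),
    ],
)
def test_settings_induce_published_betas(setting_id, expected):
    beta = beta_from_alpha(setting_alpha(setting_id, p=20)).values
    np.testing.assert_allclose(beta[:4], expected)
    np.testing.assert_allclose(beta[4:], 0.0)


def test_settings_require_four_genes():
    with pytest.raises(ValueError):
        setting_alpha(1, p=3)
    with pytest.raises(ValueError):
        SimulationSetting(setting_id="custom", p=5, n=10, sigma=0.5)  # needs alpha


def test_generate_dataset_shapes_and_determinism():
    setting = SimulationSetting(setting_id=1, p=20, n=50, sigma=0.5, seed=11)
    ds1 = generate_dataset(setting, 50)
    ds2 = generate_dataset(setting, 50)
    assert ds1.log_expr.shape == (50, 20) and ds1.response.shape == (50,)
    assert np.array_equal(ds1.log_expr, ds2.log_expr)
    assert np.array_equal(ds1.response, ds2.response)
    other = generate_dataset(setting, 50, seed=12)
    assert not np.array_equal(ds1.log_expr, other.log_expr)


def test_empirical_moments_match_the_generator():
    """Column covariance tracks V and var(y) = beta' V beta + sigma^2 at large n."""
    setting = SimulationSetting(setting_id=1, p=10, n=50, sigma=0.5, seed=3)
    ds = generate_dataset(setting, 100_000)
    V = ar1_covariance(10, 0.5)
    emp = np.cov(ds.log_expr.T)
    assert np.max(np.abs(emp - V)) < 0.02
    beta = ds.true_beta.values
    expected_var = beta @ V @ beta + 0.25
    assert np.var(ds.response) == pytest.approx(expected_var, rel=0.03)


def test_random_beta_dataset_centered_and_deterministic():
    ds1 = generate_random_beta_dataset(p=20, n=50, seed=5)
    ds2 = generate_random_beta_dataset(p=20, n=50, seed=5)
    assert abs(ds1.true_beta.values.sum()) <= 1e-12
    assert np.array_equal(ds1.response, ds2.response)
    assert ds1.log_expr.shape == (50, 20)
    # the stored pair truth is the peeled minimum-L1 representation
    assert ds1.true_alpha.l1 == pytest.approx(ds1.true_beta.l1 / 2)


def test_sample_shifts_change_row_means_and_not_sum_zero_predictions(rng):
    X = rng.standard_normal((30, 8))
    shifted, shifts = apply_sample_shifts(X, seed=9)
    np.testing.assert_allclose(shifted.mean(axis=1) - X.mean(axis=1), shifts, atol=1e-12)
    beta = rng.standard_normal(8)
    beta -= beta.mean()
    np.testing.assert_allclose(shifted @ beta, X @ beta, atol=1e-10)


def test_random_scaling_identity_and_log_structure(rng):
    X = np.exp(rng.standard_normal((10, 6)))
    same, sf, gf = apply_random_scaling(X, per_gene=False, per_sample=False, seed=1)
    np.testing.assert_array_equal(same, X)
    np.testing.assert_array_equal(sf, 1.0)
    scaled, sf, gf = apply_random_scaling(X, per_gene=True, per_sample=True, seed=1)
    # log of the scaled matrix is the original plus rank-1 row/column offsets
    np.testing.assert_allclose(
        np.log(scaled), np.log(X) + np.log(sf)[:, None] + np.log(gf)[None, :], atol=1e-12
    )
    with pytest.raises(ValueError):
        apply_random_scaling(np.array([[1.0, 0.0]]), per_gene=True, seed=0)
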