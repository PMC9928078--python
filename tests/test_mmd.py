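"""Kernel two-sample machinery: MMD, bandwidth, permutation test, baselines."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ttest_ind

from walkmmd import (
    KernelSpec,
    equalize_sizes,
    gaussian_kernel_matrix,
    hotelling_baseline,
    marginalize_by_length,
    median_bandwidth,
    mmd_u_squared,
    permutation_test,
)


def test_kernel_values():
    assert gaussian_kernel_matrix([[0.0]], [[0.0]], 1.0)[0, 0] == pytest.approx(1.0)
    assert gaussian_kernel_matrix([[0.0]], [[1.0]], 1.0)[0, 0] == pytest.approx(
        np.exp(-0.5)
    )
    with pytest.raises(ValueError):
        gaussian_kernel_matrix([[0.0]], [[1.0]], 0.0)


def test_kernel_matrix_symmetric_unit_diagonal(rng):
    A = rng.normal(size=(7, 3))
    K = gaussian_kernel_matrix(A, A, 1.3)
    assert np.allclose(K, K.T)
    assert np.allclose(np.diag(K), 1.0)
    assert np.all((K > 0) & (K <= 1))


def test_median_bandwidth_enumeration():
    assert median_bandwidth(np.array([0.0, 1.0, 3.0])) == pytest.approx(2.0)
    # {a, a, b}: distances {0, d, d} -> median d
    assert median_bandwidth(np.array([1.0, 1.0, 4.0])) == pytest.approx(3.0)


def test_median_bandwidth_homogeneity(rng):
    pts = rng.normal(size=(20, 2))
    assert median_bandwidth(5.0 * pts) == pytest.approx(5.0 * median_bandwidth(pts))


def test_median_bandwidth_degenerate():
    with pytest.raises(ValueError, match="identical"):
        median_bandwidth(np.zeros((5, 2)))


def test_mmd_identical_points_zero():
    X = np.array([[1.0, 2.0], [1.0, 2.0]])
    assert mmd_u_squared(X, X, 1.0) == pytest.approx(0.0)


def test_mmd_negative_closed_form():
    X = np.array([0.0, 1.0])
    assert mmd_u_squared(X, X, 1.0) == pytest.approx(np.exp(-0.5) - 1.0)


def test_mmd_symmetry_and_size_validation(rng):
    X = rng.normal(size=(5, 2))
    Y = rng.normal(size=(4, 2)) + 1
    assert mmd_u_squared(X, Y, 1.0) == pytest.approx(mmd_u_squared(Y, X, 1.0))
    with pytest.raises(ValueError):
        mmd_u_squared(X[:1], Y, 1.0)


def _oracle(X, Y, sigma):
    def k(a, b):
        return np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))

    m, n = len(X), len(Y)
    sxx = sum(k(X[i], X[j]) for i in range(m) for j in range(m) if i != j)
    syy = sum(k(Y[i], Y[j]) for i in range(n) for j in range(n) if i != j)
    sxy = sum(k(x, y) for x in X for y in Y)
    return sxx / (m * (m - 1)) + syy / (n * (n - 1)) - 2 * sxy / (m * n)


@settings(max_examples=60, deadline=None)
@given(
    st.integers(2, 6), st.integers(2, 6), st.integers(1, 3),
    st.integers(0, 10**6), st.floats(0.3, 3.0),
)
def test_mmd_matches_oracle(m, n, d, seed, sigma):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, d))
    Y = rng.normal(size=(n, d))
    assert mmd_u_squared(X, Y, sigma) == pytest.approx(_oracle(X, Y, sigma), abs=1e-12)


def test_equalize_sizes(rng):
    X = rng.normal(size=(300, 2))
    Y = rng.normal(size=(100, 2))
    X1, Y1 = equalize_sizes(X, Y, rng_seed=5)
    assert len(X1) == len(Y1) == 100
    assert np.array_equal(Y1, Y)
    # subsampled rows come from X
    assert all(any(np.array_equal(r, x) for x in X) for r in X1[:5])
    X2, _ = equalize_sizes(X, Y, rng_seed=5)
    assert np.array_equal(X1, X2)
    Xs, Ys = equalize_sizes(Y, Y, rng_seed=5)
    assert np.array_equal(Xs, Y) and np.array_equal(Ys, Y)


def test_marginalize_by_length(rng):
    X = rng.normal(size=(10, 2))
    Y = rng.normal(size=(9, 2))
    xl = np.full(10, 7)
    yl = np.array([7] * 4 + [8] * 5)
    X1, Y1 = marginalize_by_length(X, xl, Y, yl, rng_seed=0)
    assert len(X1) == len(Y1) == 4

    # identical histograms -> unchanged
    X2, Y2 = marginalize_by_length(X, xl, Y[:4], yl[:4] * 0 + 7, rng_seed=0)
    assert len(X2) == 4 and len(Y2) == 4

    with pytest.raises(ValueError, match="no comparable"):
        marginalize_by_length(X, xl, Y, np.full(9, 20), rng_seed=0)


def test_marginalize_counts_match(rng):
    xl = rng.integers(7, 12, 80)
    yl = rng.integers(7, 12, 60)
    X = rng.normal(size=(80, 2))
    Y = rng.normal(size=(60, 2))
    X1, Y1 = marginalize_by_length(X, xl, Y, yl, rng_seed=1)
    assert len(X1) == len(Y1)


def test_permutation_identical_multiset_not_rejected(rng):
    X = rng.normal(size=(30, 2))
    res = permutation_test(X, X.copy(), B=200, rng_seed=0)
    assert not res.reject
    assert res.p_value > 0.5


def test_permutation_separated_gaussians(rng):
    X = rng.normal(size=(100, 2))
    Y = rng.normal(size=(100, 2)) + 10.0
    res = permutation_test(X, Y, B=500, rng_seed=1)
    assert res.reject
    assert res.p_value == pytest.approx(1.0 / 501.0)


def test_permutation_determinism_and_contract(rng):
    X = rng.normal(size=(40, 2))
    Y = rng.normal(size=(40, 2))
    r1 = permutation_test(X, Y, B=300, rng_seed=7)
    r2 = permutation_test(X, Y, B=300, rng_seed=7)
    assert r1.mmd_u2 == r2.mmd_u2
    assert np.array_equal(r1.null_samples, r2.null_samples)
    assert 0 < r1.p_value <= 1
    assert r1.m == r1.n == 40
    assert len(r1.null_samples) == 300
    want = r1.mmd_u2 > np.quantile(r1.null_samples, 0.95)
    assert r1.reject == want
    with pytest.raises(ValueError):
        permutation_test(X, Y, B=0)


def test_permutation_null_matches_direct_statistic(rng):
    """The vectorized permutation statistics equal direct re-evaluation."""
    X = rng.normal(size=(12, 2))
    Y = rng.normal(size=(10, 2))
    res = permutation_test(X, Y, kernel=1.0, B=50, rng_seed=3)
    pooled = np.vstack([X, Y])
    nulls = []
    perm_rng = np.random.default_rng(3)
    for _ in range(50):
        perm = perm_rng.permutation(22)
        nulls.append(mmd_u_squared(pooled[perm[:12]], pooled[perm[12:]], 1.0))
    assert np.allclose(sorted(res.null_samples), sorted(nulls), atol=1e-12)


def test_p_values_super_uniform_under_h0(rng):
    # under H0 the permutation p-value is (super-)uniform: the ECDF at 0.05
    # must not exceed 0.05 plus a ~3.6-sigma binomial margin at 1000 reps
    reps = 1000
    ps = []
    for _ in range(reps):
        X = rng.normal(size=(25, 2))
        Y = rng.normal(size=(25, 2))
        res = permutation_test(X, Y, B=200, rng_seed=rng.integers(2**31))
        ps.append(res.p_value)
    ps = np.array(ps)
    assert (ps <= 0.05).mean() <= 0.075
    assert 0.4 < (ps <= 0.5).mean() < 0.6


def test_hotelling_identical_sets(rng):
    X = rng.normal(size=(20, 2))
    t2, p = hotelling_baseline(X, X.copy())
    assert t2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_hotelling_reduces_to_t_test_in_1d(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=35) + 0.3
    t2, p = hotelling_baseline(x, y)
    t_stat, p_t = ttest_ind(x, y, equal_var=True)
    assert t2 == pytest.approx(t_stat**2)
    assert p == pytest.approx(p_t)


def test_hotelling_validation(rng):
    X = np.column_stack([rng.normal(size=20), rng.normal(size=20)])
    Xdup = np.column_stack([X[:, 0], X[:, 0]])  # singular pooled covariance
    with pytest.raises(ValueError, match="singular|regulariz"):
        hotelling_baseline(Xdup, Xdup + 0.0)
    with pytest.raises(ValueError, match="dimension"):
        hotelling_baseline(rng.normal(size=(4, 5)), rng.normal(size=(4, 5)))


def test_kernel_spec_validation():
    with pytest.raises(ValueError):
        KernelSpec(-1.0)
    assert KernelSpec().resolve(np.array([[0.0], [1.0], [3.0]])) == pytest.approx(2.0)
    assert KernelSpec(1.5).resolve(np.zeros((3, 1))) == 1.5
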