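"""Kernel two-sample testing with the maximum mean discrepancy (MMD).

The unbiased squared-MMD statistic between feature sets X (size m) and
Y (size n) is

    MMD_u^2 = 1/(m(m-1)) sum_{i != j} k(x_i, x_j)
            + 1/(n(n-1)) sum_{i != j} k(y_i, y_j)
            - 2/(mn)     sum_{i, j}   k(x_i, y_j)

with a Gaussian kernel ``k(a, b) = exp(-||a-b||^2 / (2 sigma^2))`` whose
bandwidth defaults to the median of the pooled pairwise distances. The
statistic may be negative (unbiasedness). Significance is assessed with a
permutation test: the pooled sample is randomly re-partitioned B times into
groups of the original sizes, and the null hypothesis p = q is rejected at
level beta iff the observed statistic exceeds the empirical (1 - beta)
quantile of the permutation distribution.

Any constant amplitude prefactor of the kernel rescales MMD_u^2 uniformly
and cancels in the permutation test; the unit-amplitude Gaussian is used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import f as f_dist

MEDIAN = "median"


@dataclass
class KernelSpec:
    """Gaussian kernel with a fixed or median-heuristic bandwidth."""

    bandwidth: object = MEDIAN  # positive float or the "median" sentinel

    def __post_init__(self) -> None:
        if self.bandwidth != MEDIAN and not (float(self.bandwidth) > 0):
            raise ValueError("bandwidth must be positive or 'median'")

    def resolve(self, pooled: np.ndarray) -> float:
        if self.bandwidth == MEDIAN:
            return median_bandwidth(pooled)
        return float(self.bandwidth)


@dataclass
class MMDTestResult:
    """Outcome of the MMD permutation test."""

    mmd_u2: float
    null_samples: np.ndarray
    p_value: float
    reject: bool
    beta: float
    m: int
    n: int
    bandwidth: float
    rng_seed: object = None


def _as_2d(a) -> np.ndarray:
    """Coerce a feature set to (n, d); 1-D input becomes a column."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def gaussian_kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel Gram matrix between two point sets."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = _as_2d(A)
    B = _as_2d(B)
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def median_bandwidth(points: np.ndarray) -> float:
    """Median of the pairwise Euclidean distances of the pooled sample."""
    points = _as_2d(points)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    med = float(np.median(pdist(points)))
    if med <= 0:
        raise ValueError(
            "all points identical: median bandwidth undefined, "
            "pass an explicit bandwidth"
        )
    return med


def mmd_u_squared(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec | float = MEDIAN) -> float:
    """Unbiased squared MMD between feature sets X and Y."""
    X = _as_2d(X)
    Y = _as_2d(Y)
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("both sets need at least 2 points")
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(kernel)
    sigma = kernel.resolve(np.vstack([X, Y]))
    kxx = gaussian_kernel_matrix(X, X, sigma)
    kyy = gaussian_kernel_matrix(Y, Y, sigma)
    kxy = gaussian_kernel_matrix(X, Y, sigma)
    term_x = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    term_y = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    term_xy = 2.0 * kxy.sum() / (m * n)
    return float(term_x + term_y - term_xy)


def equalize_sizes(X: np.ndarray, Y: np.ndarray, rng_seed=None):
    """Randomly subsample the larger set (without replacement) to the
    smaller set's size; the smaller set is returned unchanged."""
    X = _as_2d(X)
    Y = _as_2d(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("both sets must be non-empty")
    rng = np.random.default_rng(rng_seed)
    if len(X) > len(Y):
        X = X[rng.choice(len(X), size=len(Y), replace=False)]
    elif len(Y) > len(X):
        Y = Y[rng.choice(len(Y), size=len(X), replace=False)]
    return X, Y


def marginalize_by_length(X, x_lengths, Y, y_lengths, rng_seed=None):
    """Match the trajectory-length histograms of two feature sets.

    For each integer length, both sets are randomly subsampled (without
    replacement) to the minimum of their counts at that length; lengths
    present in only one set are dropped. Returns the matched
    ``(X', Y')`` feature arrays, whose per-length counts are identical.
    """
    X = _as_2d(X)
    Y = _as_2d(Y)
    x_lengths = np.asarray(x_lengths)
    y_lengths = np.asarray(y_lengths)
    rng = np.random.default_rng(rng_seed)
    keep_x, keep_y = [], []
    for length in np.intersect1d(np.unique(x_lengths), np.unique(y_lengths)):
        ix = np.flatnonzero(x_lengths == length)
        iy = np.flatnonzero(y_lengths == length)
        k = min(len(ix), len(iy))
        keep_x.append(rng.choice(ix, size=k, replace=False))
        keep_y.append(rng.choice(iy, size=k, replace=False))
    if not keep_x:
        raise ValueError("no comparable trajectories: length supports are disjoint")
    return X[np.sort(np.concatenate(keep_x))], Y[np.sort(np.concatenate(keep_y))]


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    kernel: KernelSpec | float = MEDIAN,
    B: int = 1000,
    beta: float = 0.05,
    rng_seed=None,
) -> MMDTestResult:
    """MMD permutation (bootstrap) test of H0: p = q at level ``beta``.

    The null distribution comes from ``B`` random re-partitions of the pooled
    sample into groups of the original sizes; the bandwidth is resolved once
    on the pooled observed sample and reused for every permutation. The
    reported p-value uses the +1 correction, ``p = (1 + #{null >= obs}) /
    (B + 1)``, so it is never zero.
    """
    X = _as_2d(X)
    Y = _as_2d(Y)
    if B < 1:
        raise ValueError("B must be >= 1")
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("both sets need at least 2 points")
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(kernel)
    pooled = np.vstack([X, Y])
    sigma = kernel.resolve(pooled)
    K = gaussian_kernel_matrix(pooled, pooled, sigma)
    observed = _mmd_from_gram(K, np.arange(m), np.arange(m, m + n))

    rng = np.random.default_rng(rng_seed)
    total = m + n
    # one (total, B) indicator matrix lets BLAS evaluate all permutations
    U = np.empty((total, B))
    for b in range(B):
        perm = rng.permutation(total)
        col = np.zeros(total)
        col[perm[:m]] = 1.0
        U[:, b] = col
    KU = K @ U  # (total, B)
    ones = np.ones(total)
    row_tot = K @ ones  # (total,)
    sxx = np.einsum("ib,ib->b", U, KU) - m  # subtract unit diagonal
    uK1 = np.einsum("ib,i->b", U, row_tot)  # u^T K 1 = u^T K u + u^T K v
    sxy = uK1 - (sxx + m)
    syy = K.sum() - 2 * uK1 + (sxx + m) - n
    null = (
        sxx / (m * (m - 1))
        + syy / (n * (n - 1))
        - 2.0 * sxy / (m * n)
    )
    p_value = float((1 + np.sum(null >= observed)) / (B + 1))
    reject = bool(observed > np.quantile(null, 1.0 - beta))
    return MMDTestResult(
        mmd_u2=float(observed),
        null_samples=null,
        p_value=p_value,
        reject=reject,
        beta=beta,
        m=m,
        n=n,
        bandwidth=sigma,
        rng_seed=rng_seed,
    )


def _mmd_from_gram(K, idx_x, idx_y):
    m, n = len(idx_x), len(idx_y)
    kxx = K[np.ix_(idx_x, idx_x)]
    kyy = K[np.ix_(idx_y, idx_y)]
    kxy = K[np.ix_(idx_x, idx_y)]
    return (
        (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
        + (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
        - 2.0 * kxy.sum() / (m * n)
    )


def hotelling_baseline(X: np.ndarray, Y: np.ndarray):
    """Two-sample Hotelling T^2 test (pooled covariance, F p-value).

    In one dimension this reduces to the squared two-sample t statistic.
    Returns ``(T2, p_value)``.
    """
    X = _as_2d(X)
    Y = _as_2d(Y)
    m, n = len(X), len(Y)
    d = X.shape[1]
    if d >= min(m, n) - 1:
        raise ValueError("dimension too high for the sample sizes")
    diff = X.mean(axis=0) - Y.mean(axis=0)
    Sx = np.cov(X, rowvar=False).reshape(d, d)
    Sy = np.cov(Y, rowvar=False).reshape(d, d)
    S = ((m - 1) * Sx + (n - 1) * Sy) / (m + n - 2)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; consider regularizing the features"
        ) from exc
    t2 = float(m * n / (m + n) * diff @ sol)
    df2 = m + n - 1 - d
    f_stat = t2 * df2 / ((m + n - 2) * d)
    p = float(f_dist.sf(f_stat, d, df2))
    return t2, p
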