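"""Many-group comparison: pairwise MMD distances and uncertainty-aware MDS.

Groups of trajectories (e.g. individual synapses) are compared all-to-all by
the unbiased squared MMD of their feature sets, giving a squared-distance
matrix plus a per-entry variance estimate that shrinks with group size.
The groups are then embedded in a low-dimensional Euclidean space by
weighted-stress multidimensional scaling, with weights proportional to the
inverse variances so that poorly-estimated distances constrain the
configuration less.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mmd import MEDIAN, KernelSpec, equalize_sizes, mmd_u_squared

#: default minimum trajectories per group (the synapse-analysis filter)
MIN_TRAJECTORIES = 150


@dataclass
class GroupDistanceMatrix:
    """Pairwise squared MMD distances between trajectory groups."""

    group_ids: list
    squared_distances: np.ndarray  # (g, g), signed MMD_u^2 values
    variances: np.ndarray  # (g, g) per-entry uncertainty
    counts: np.ndarray  # (g,) trajectories per group
    min_trajectories: int = MIN_TRAJECTORIES


@dataclass
class GroupEmbedding:
    """Euclidean embedding of the groups with its final weighted stress."""

    group_ids: list
    coordinates: np.ndarray  # (g, embed_dim)
    stress: float
    rng_seed: object = None


def estimate_mmd_variance(
    X: np.ndarray,
    Y: np.ndarray,
    kernel: KernelSpec | float = MEDIAN,
    n_subsamples: int = 50,
    rng_seed=None,
) -> float:
    """Variance of the MMD_u^2 estimate by half-subsampling.

    The statistic is recomputed on ``n_subsamples`` random half-size
    subsamples of each set; the observed variance is rescaled to the full
    sizes by the U-statistic 1/n rate (half sizes double the variance, so
    the full-size variance is half the subsampled one).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) < 4 or len(Y) < 4:
        raise ValueError("need at least 4 points per set")
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(kernel)
    sigma = kernel.resolve(np.vstack([X, Y]))
    rng = np.random.default_rng(rng_seed)
    hm, hn = len(X) // 2, len(Y) // 2
    vals = np.empty(n_subsamples)
    for i in range(n_subsamples):
        xs = X[rng.choice(len(X), hm, replace=False)]
        ys = Y[rng.choice(len(Y), hn, replace=False)]
        vals[i] = mmd_u_squared(xs, ys, sigma)
    return float(vals.var(ddof=1) / 2.0)


def pairwise_group_mmd(
    feature_sets: dict,
    kernel: KernelSpec | float = MEDIAN,
    min_trajectories: int = MIN_TRAJECTORIES,
    rng_seed=None,
    n_subsamples: int = 50,
) -> GroupDistanceMatrix:
    """All-pairs MMD_u^2 between groups' feature sets.

    ``feature_sets`` maps group id -> (n_i, d) feature array. Groups with
    fewer than ``min_trajectories`` members are dropped; each pair is size-
    equalized by subsampling the larger set before computing the statistic
    and its variance.
    """
    kept = {g: np.asarray(f, dtype=float) for g, f in feature_sets.items()
            if len(f) >= min_trajectories}
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 groups have >= {min_trajectories} trajectories"
        )
    ids = list(kept)
    g = len(ids)
    rng = np.random.default_rng(rng_seed)
    D2 = np.zeros((g, g))
    V = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            X, Y = equalize_sizes(kept[ids[i]], kept[ids[j]], rng.integers(2**31))
            D2[i, j] = D2[j, i] = mmd_u_squared(X, Y, kernel)
            V[i, j] = V[j, i] = estimate_mmd_variance(
                X, Y, kernel, n_subsamples=n_subsamples, rng_seed=rng.integers(2**31)
            )
    counts = np.array([len(kept[i]) for i in ids])
    return GroupDistanceMatrix(ids, D2, V, counts, min_trajectories)


def _weighted_smacof(D, W, dim, rng, n_iter=300, tol=1e-9):
    """One weighted-stress majorization run; returns (coords, stress)."""
    g = len(D)
    Z = rng.normal(0.0, np.nanmax(D) / 2 + 1e-12, (g, dim))
    Vmat = np.diag(W.sum(axis=1)) - W
    Vpinv = np.linalg.pinv(Vmat)

    def distances(Z):
        diff = Z[:, None, :] - Z[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))

    def stress(dz):
        return 0.5 * np.sum(W * (dz - D) ** 2)

    dz = distances(Z)
    prev = stress(dz)
    for _ in range(n_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dz > 0, D / np.maximum(dz, 1e-300), 0.0)
        Bmat = -W * ratio
        np.fill_diagonal(Bmat, 0.0)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        Z = Vpinv @ (Bmat @ Z)
        dz = distances(Z)
        cur = stress(dz)
        if prev - cur < tol * max(prev, 1.0):
            prev = cur
            break
        prev = cur
    return Z, float(prev)


def mds_with_uncertainty(
    matrix: GroupDistanceMatrix,
    embed_dim: int = 3,
    rng_seed=None,
    n_restarts: int = 4,
) -> GroupEmbedding:
    """Embed groups by inverse-variance-weighted stress majorization.

    Negative (unbiased) squared distances are clamped to zero before taking
    square roots; weights are proportional to 1 / variance (normalised).
    The best of ``n_restarts`` random initializations is kept; reproducible
    from ``rng_seed``.
    """
    if embed_dim < 1:
        raise ValueError("embed_dim must be >= 1")
    D = np.sqrt(np.maximum(matrix.squared_distances, 0.0))
    V = matrix.variances.copy()
    off = ~np.eye(len(D), dtype=bool)
    if not np.all(np.isfinite(V[off])) or np.any(V[off] < 0):
        raise ValueError("variances must be finite and non-negative")
    floor = max(np.median(V[off]) * 1e-6, 1e-300)
    W = 1.0 / np.maximum(V, floor)
    np.fill_diagonal(W, 0.0)
    W /= W[off].mean()
    rng = np.random.default_rng(rng_seed)
    best = None
    for _ in range(max(1, n_restarts)):
        Z, s = _weighted_smacof(D, W, embed_dim, rng)
        if best is None or s < best[1]:
            best = (Z, s)
    Z, s = best
    Z = Z - Z.mean(axis=0)
    return GroupEmbedding(matrix.group_ids, Z, s, rng_seed)
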