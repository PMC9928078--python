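"""Interpretation of MMD differences in the latent plane.

The witness function is the empirical maximizer of the MMD: the difference
of the kernel mean embeddings of the two samples,

    f(z) = 1/m sum_i k(x_i, z) - 1/n sum_j k(y_j, z).

Its sign says which condition predominates at a point of the plane; its
amplitude, how strongly. The S statistic normalises the squared witness
amplitude by its bootstrap variance, S(z) = mean(f(z))^2 / var(f(z)); the
"critical region" of a condition is the connected component of
{S >= 3/4 max S} around the S maximum on that condition's side of the
witness, the type of trajectories most responsible for the detected
difference. Representative tracks are pulled out as the nearest
trajectories to a latent-space point (16 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .mmd import MEDIAN, KernelSpec, gaussian_kernel_matrix

logger = logging.getLogger(__name__)

DEFAULT_GRID = 100
#: additive variance regularization for the S statistic, as a fraction of the
#: maximal bootstrap variance over the grid. The bootstrap variance scales
#: with the local kernel density, so far from any data both the witness mean
#: and its variance vanish and their raw ratio is pure noise; the additive
#: term drives S to zero there while changing it by at most a factor
#: 1 / (1 + S_VARIANCE_REG) where the data lives.
S_VARIANCE_REG = 1e-3


@dataclass
class WitnessField:
    """Gridded witness function over the latent plane (and optionally S)."""

    grid_x: np.ndarray  # (gx,) cell-center coordinates
    grid_y: np.ndarray  # (gy,)
    witness: np.ndarray  # (gx, gy)
    s_values: np.ndarray | None = None  # (gx, gy), >= 0
    critical_regions: list = field(default_factory=list)  # (label, mask) pairs
    max_locations: list = field(default_factory=list)  # (label, (x, y)) pairs


def make_grid(points: np.ndarray, n: int = DEFAULT_GRID, margin: float = 0.1):
    """Regular n x n lattice spanning the pooled data range plus a margin."""
    points = np.asarray(points, dtype=float)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = margin * (hi - lo)
    pad[pad == 0] = 1.0
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n)
    return gx, gy


def _grid_points(gx, gy):
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    return np.column_stack([mx.ravel(), my.ravel()])


def witness_function(
    X: np.ndarray,
    Y: np.ndarray,
    kernel: KernelSpec | float = MEDIAN,
    grid=None,
    n_grid: int = DEFAULT_GRID,
) -> WitnessField:
    """Evaluate the empirical witness function on a grid over the plane.

    Swapping X and Y negates the field. ``grid`` may be a precomputed
    ``(grid_x, grid_y)`` pair; otherwise an ``n_grid`` x ``n_grid`` lattice
    over the pooled data (plus 10% margin) is used.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(kernel)
    sigma = kernel.resolve(np.vstack([X, Y]))
    gx, gy = grid if grid is not None else make_grid(np.vstack([X, Y]), n_grid)
    if len(gx) == 0 or len(gy) == 0:
        raise ValueError("empty grid")
    pts = _grid_points(gx, gy)
    fx = gaussian_kernel_matrix(X, pts, sigma).mean(axis=0)
    fy = gaussian_kernel_matrix(Y, pts, sigma).mean(axis=0)
    return WitnessField(gx, gy, (fx - fy).reshape(len(gx), len(gy)))


def s_statistic_map(
    X: np.ndarray,
    Y: np.ndarray,
    kernel: KernelSpec | float = MEDIAN,
    grid=None,
    n_grid: int = DEFAULT_GRID,
    n_boot: int = 200,
    rng_seed=None,
) -> WitnessField:
    """Witness field plus the bootstrap S statistic on the same grid.

    Bootstrap resamples (with replacement, within each set) give the
    per-grid-point mean and variance of the witness; S = mean^2 / var with
    the variance regularized by a small fraction of its grid maximum so that
    S vanishes far from the data instead of amplifying numerical noise.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(kernel)
    sigma = kernel.resolve(np.vstack([X, Y]))
    gx, gy = grid if grid is not None else make_grid(np.vstack([X, Y]), n_grid)
    pts = _grid_points(gx, gy)
    Kx = gaussian_kernel_matrix(X, pts, sigma)  # (m, G)
    Ky = gaussian_kernel_matrix(Y, pts, sigma)  # (n, G)
    m, n = len(X), len(Y)
    rng = np.random.default_rng(rng_seed)
    # multiplicity-count matrices turn each bootstrap mean into one matmul
    Cx = np.zeros((n_boot, m))
    Cy = np.zeros((n_boot, n))
    for b in range(n_boot):
        np.add.at(Cx[b], rng.integers(0, m, m), 1.0)
        np.add.at(Cy[b], rng.integers(0, n, n), 1.0)
    if np.all(Cx == Cx[0]) and np.all(Cy == Cy[0]):
        raise ValueError("degenerate bootstrap: identical resamples")
    F = Cx @ Kx / m - Cy @ Ky / n  # (n_boot, G) witness per resample
    mean_f = F.mean(axis=0)
    var_f = F.var(axis=0, ddof=1)
    witness = (Kx.mean(axis=0) - Ky.mean(axis=0)).reshape(len(gx), len(gy))
    reg = S_VARIANCE_REG * max(np.max(var_f), np.finfo(float).tiny)
    s = (mean_f**2) / (var_f + reg)
    return WitnessField(gx, gy, witness, s_values=s.reshape(len(gx), len(gy)))


def critical_region(
    fld: WitnessField,
    threshold_frac: float = 0.75,
    labels=("X", "Y"),
) -> WitnessField:
    """Extract per-condition critical regions from an S field.

    For each witness sign (positive: first condition predominates; negative:
    second), the connected component of ``{S >= threshold_frac * max S}``
    containing that side's S maximum, intersected with that side of the
    witness. Populates ``fld.critical_regions`` with (label, boolean mask)
    and ``fld.max_locations`` with the S-argmax coordinates per side.
    """
    if fld.s_values is None:
        raise ValueError("compute the S statistic first")
    s = fld.s_values
    if np.allclose(s, s.flat[0]):
        logger.warning("flat S field: no critical region")
        fld.critical_regions = []
        return fld
    thr = threshold_frac * s.max()
    fld.critical_regions = []
    fld.max_locations = []
    for sign, label in zip((1.0, -1.0), labels):
        side = sign * fld.witness > 0
        if not np.any(side & (s >= thr)):
            continue
        s_side = np.where(side, s, -np.inf)
        peak = np.unravel_index(np.argmax(s_side), s.shape)
        comp = measure.label((s >= thr) & side)
        mask = comp == comp[peak]
        fld.critical_regions.append((label, mask))
        fld.max_locations.append(
            (label, (fld.grid_x[peak[0]], fld.grid_y[peak[1]]))
        )
    return fld


def points_in_region(points: np.ndarray, fld: WitnessField, mask: np.ndarray) -> np.ndarray:
    """Boolean membership of 2D points in a gridded region mask
    (nearest-cell lookup)."""
    points = np.asarray(points, dtype=float)
    ix = np.clip(np.searchsorted(fld.grid_x, points[:, 0]), 0, len(fld.grid_x) - 1)
    iy = np.clip(np.searchsorted(fld.grid_y, points[:, 1]), 0, len(fld.grid_y) - 1)
    return mask[ix, iy]


def nearest_trajectories(point, latents2d: np.ndarray, track_ids, count: int = 16):
    """Ids of the ``count`` nearest latent points to ``point``.

    Euclidean distance; ties broken by ascending trajectory id. If ``count``
    exceeds the table size all ids are returned (with a warning).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    latents2d = np.asarray(latents2d, dtype=float)
    track_ids = np.asarray(track_ids)
    d = np.linalg.norm(latents2d - np.asarray(point, dtype=float), axis=1)
    order = np.lexsort((track_ids, d))
    if count > len(track_ids):
        logger.warning("count %d exceeds table size %d", count, len(track_ids))
        count = len(track_ids)
    return track_ids[order[:count]]
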