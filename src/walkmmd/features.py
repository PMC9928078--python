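"""Classical per-trajectory descriptors.

These are the analytic baselines against which the learnt summary statistics
are compared: the apparent effective diffusivity and three geometric shape
descriptors (Katz fractal dimension, convex-hull area, gyration asymmetry).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .trajectory import Trajectory, TrajectoryGroup

logger = logging.getLogger(__name__)

#: sentinel for log10(D) when the displacement variance is exactly zero
LOG10_D_FLOOR = -12.0


def effective_diffusivity(traj: Trajectory) -> float:
    """Apparent effective diffusivity from single-time-lapse displacements.

    ``D_hat = sum_i ||dr_i - mu||^2 / (4 (N - 1) dt)`` with
    ``mu = sum_i dr_i / N``, where ``dr_i`` are the one-step displacements and
    ``N`` here counts displacements (so a trajectory needs at least two
    displacements, i.e. three points). Units: um^2/s for positions in um.
    """
    dr = traj.displacements
    n = len(dr)
    if n < 2:
        raise ValueError("effective diffusivity needs at least 2 displacements")
    mu = dr.mean(axis=0)
    ss = np.sum((dr - mu) ** 2)
    return float(ss / (4.0 * (n - 1) * traj.dt))


def katz_fractal_dimension(traj: Trajectory) -> float:
    """Katz's estimator of the fractal dimension of a planar curve.

    ``FD = log(n) / (log(n) + log(d / L))`` with ``L`` the total path length,
    ``d`` the maximal distance from the first point and ``n`` the number of
    steps. Equals 1 for a straight path, grows with tortuosity.
    """
    dr = traj.displacements
    L = np.linalg.norm(dr, axis=1).sum()
    d = np.linalg.norm(traj.positions - traj.positions[0], axis=1).max()
    n = len(dr)
    if L == 0 or d == 0:
        return 1.0
    return float(np.log(n) / (np.log(n) + np.log(d / L)))


def convex_hull_area(traj: Trajectory) -> float:
    """Area (um^2) of the convex hull of the localizations; 0 if collinear."""
    try:
        return float(ConvexHull(traj.positions).volume)  # 2D: volume == area
    except QhullError:
        return 0.0


def asymmetry(traj: Trajectory) -> float:
    """Gyration-tensor asymmetry: 1 - lambda_min / lambda_max, in [0, 1].

    1 for a perfectly straight (degenerate) path, small for isotropic ones.
    """
    pos = traj.positions - traj.positions.mean(axis=0)
    gyr = pos.T @ pos / len(pos)
    lam = np.linalg.eigvalsh(gyr)
    if lam[1] <= 0:
        return 1.0
    return float(1.0 - lam[0] / lam[1])


def classical_features(traj: Trajectory) -> np.ndarray:
    """4-vector [log10 D_hat, Katz fractal dimension, hull area, asymmetry]."""
    if len(traj) < 4:
        raise ValueError("classical features need at least 4 points")
    d_hat = effective_diffusivity(traj)
    if d_hat > 0:
        log_d = np.log10(d_hat)
    else:
        logger.warning("track %s: zero displacement variance, log10(D) floored",
                       traj.track_id)
        log_d = LOG10_D_FLOOR
    return np.array(
        [log_d, katz_fractal_dimension(traj), convex_hull_area(traj), asymmetry(traj)]
    )


def classical_feature_table(group: TrajectoryGroup) -> np.ndarray:
    """Stack classical features for a group into an (n, 4) array."""
    return np.vstack([classical_features(t) for t in group])
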