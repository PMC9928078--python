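"""Directed feature graphs over trajectories.

Each trajectory of N points becomes a directed graph whose nodes are the
localizations and whose edges point forward in time. Node ``i`` (1-based)
receives edges from nodes ``i - floor(gamma^j)`` for ``j = 0..k-1`` with
``gamma = (i-1)^(1/(k-1))``: a geometric fan-in mixing short- and long-range
history, capped at in-degree ``k`` (default 10). Trajectories shorter than
``k`` wire every node to all its predecessors.

Node and edge features are scale-free (power sums of step sizes and
distances normalised by the trajectory's RMS one-step displacement); the
global scale enters separately as ``log10`` of that RMS displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

DEFAULT_K = 10

N_NODE_FEATURES = 6
N_EDGE_FEATURES = 6


class DegenerateTrajectoryError(ValueError):
    """All positions identical: no scale can be defined."""


@dataclass
class TrajGraph:
    """Graph representation of one trajectory (0-based node indices)."""

    num_nodes: int
    edges: np.ndarray  # (|E|, 2) int array of (source, target), source < target
    node_features: np.ndarray  # (N, 6)
    edge_features: np.ndarray  # (|E|, 6)
    scale: float  # log10 of the RMS one-step displacement
    track_id: object = None

    def __post_init__(self) -> None:
        assert self.node_features.shape == (self.num_nodes, N_NODE_FEATURES)
        assert self.edge_features.shape == (len(self.edges), N_EDGE_FEATURES)


def build_edge_index(n: int, k: int = DEFAULT_K) -> np.ndarray:
    """Edge list (0-based, (source, target), source < target) for N nodes.

    Implements the geometric fan-in wiring described above; for ``n < k``
    every node is connected to all its predecessors. Duplicate offsets are
    removed.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if k < 2:
        raise ValueError("k must be >= 2")
    edges = []
    for i in range(2, n + 1):  # 1-based target index
        if n < k:
            offsets = range(1, i)
        else:
            gamma = (i - 1) ** (1.0 / (k - 1))
            offsets = sorted({int(np.floor(gamma**j)) for j in range(k)})
        for off in offsets:
            src = i - off
            if src >= 1:
                edges.append((src - 1, i - 1))
    return np.array(sorted(set(edges)), dtype=int)


def trajectory_scale(traj: Trajectory) -> float:
    """RMS one-step displacement (um); the graph's single scale carrier."""
    dr = traj.displacements
    s = float(np.sqrt(np.mean(np.sum(dr**2, axis=1))))
    return s


def node_features(traj: Trajectory, scale: float) -> np.ndarray:
    """N x 6 node-feature matrix.

    Row ``i`` (1-based): normalised time ``(i-1)/(N-1)``; cumulative step-size
    sums to powers 1, 2, 4 normalised by ``(i * s^p)``; distance to origin and
    running maximal distance to origin, both normalised by ``s``.
    The first row is identically zero.
    """
    if scale <= 0:
        raise DegenerateTrajectoryError("zero trajectory scale")
    pos = traj.positions
    n = len(pos)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)  # |dr_j|, j = 2..N
    feats = np.zeros((n, N_NODE_FEATURES))
    i = np.arange(1, n + 1, dtype=float)
    feats[:, 0] = (i - 1) / (n - 1)
    for col, p in zip((1, 2, 3), (1, 2, 4)):
        csum = np.concatenate([[0.0], np.cumsum(step**p)])
        feats[:, col] = csum / (i * scale**p)
    dist = np.linalg.norm(pos - pos[0], axis=1)
    feats[:, 4] = dist / scale
    feats[:, 5] = np.maximum.accumulate(dist) / scale
    return feats


def edge_features(traj: Trajectory, edges: np.ndarray, scale: float) -> np.ndarray:
    """|E| x 6 edge-feature matrix for edges (j -> i), 0-based indices.

    Per edge: normalised time difference ``(i-j)/(N-1)``; normalised distance
    ``|r_i - r_j| / s``; step-size sums over the spanned interval to powers
    1, 2, 4 normalised by ``((i-j) * s^p)``; cosine similarity of the
    displacements arriving at the two endpoints (0 when undefined).
    """
    if scale <= 0:
        raise DegenerateTrajectoryError("zero trajectory scale")
    pos = traj.positions
    n = len(pos)
    dr = np.diff(pos, axis=0)
    step = np.linalg.norm(dr, axis=1)
    csums = {p: np.concatenate([[0.0], np.cumsum(step**p)]) for p in (1, 2, 4)}

    src = edges[:, 0]
    tgt = edges[:, 1]
    span = (tgt - src).astype(float)
    feats = np.zeros((len(edges), N_EDGE_FEATURES))
    feats[:, 0] = span / (n - 1)
    feats[:, 1] = np.linalg.norm(pos[tgt] - pos[src], axis=1) / scale
    for col, p in zip((2, 3, 4), (1, 2, 4)):
        feats[:, col] = (csums[p][tgt] - csums[p][src]) / (span * scale**p)
    # arriving displacement at node m (0-based) is dr[m-1]; undefined at m=0
    valid = src >= 1
    a = np.zeros((len(edges), 2))
    a[valid] = dr[src[valid] - 1]
    b = dr[tgt - 1]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = valid & (na > 0) & (nb > 0)
    feats[ok, 5] = np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok])
    return feats


def trajectory_to_graph(traj: Trajectory, k: int = DEFAULT_K) -> TrajGraph:
    """Assemble the full feature graph of one trajectory.

    The feature matrices are invariant to rigid motions and to dilation of
    the positions; dilation by ``c`` only shifts the ``scale`` field by
    ``log10 c``.
    """
    s = trajectory_scale(traj)
    if s <= 0:
        raise DegenerateTrajectoryError(
            f"track {traj.track_id}: all positions identical"
        )
    edges = build_edge_index(len(traj), k)
    return TrajGraph(
        num_nodes=len(traj),
        edges=edges,
        node_features=node_features(traj, s),
        edge_features=edge_features(traj, edges, s),
        scale=float(np.log10(s)),
        track_id=traj.track_id,
    )
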