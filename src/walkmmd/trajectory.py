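"""Trajectory containers and delimited-text I/O.

Positions are in micrometres, times in seconds. A trajectory is an ordered
sequence of 2D localizations recorded at a uniform time lapse ``dt``; it is
the atomic unit of every downstream computation (featurization, graph
construction, encoding, testing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerance (seconds) for non-uniform frame intervals within one track.
DT_TOLERANCE = 1e-6

DEFAULT_COLUMN_MAP = {
    "track_id": "track_id",
    "t": "t",
    "x": "x",
    "y": "y",
}


class TrajectoryFormatError(ValueError):
    """A trajectory table is missing mandatory columns."""


class TrajectoryValidationError(ValueError):
    """A parsed track violates the uniform-time-lapse contract."""


@dataclass
class Trajectory:
    """An ordered 2D single-particle track with uniform time lapse.

    Parameters
    ----------
    positions : (N, 2) array of float
        Localizations in micrometres, ordered by time. N >= 2.
    dt : float
        Time lapse between consecutive points, seconds (> 0).
    track_id : str or int
        Identifier of the track.
    meta : dict
        Optional labels (condition, region, and for simulated data the
        ground-truth model, alpha, diffusivity and noise sd).
    """

    positions: np.ndarray
    dt: float
    track_id: object = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrajectoryValidationError(
                f"track {self.track_id}: positions must be (N, 2), got "
                f"{self.positions.shape}"
            )
        if len(self.positions) < 2:
            raise TrajectoryValidationError(
                f"track {self.track_id}: need at least 2 points"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryValidationError(
                f"track {self.track_id}: non-finite positions"
            )
        if not (self.dt > 0):
            raise TrajectoryValidationError(
                f"track {self.track_id}: dt must be positive, got {self.dt}"
            )
        self.dt = float(self.dt)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def displacements(self) -> np.ndarray:
        """(N-1, 2) array of one-step displacements r_i - r_{i-1}."""
        return np.diff(self.positions, axis=0)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.positions) - 1) * self.dt


@dataclass
class TrajectoryGroup:
    """A labelled set of trajectories sharing a common time lapse."""

    trajectories: list
    label: object = None

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("TrajectoryGroup must be non-empty")
        dts = {round(t.dt, 12) for t in self.trajectories}
        if len(dts) > 1:
            raise TrajectoryValidationError(
                f"group {self.label!r}: trajectories have differing dt: {sorted(dts)}"
            )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]

    @property
    def dt(self) -> float:
        return self.trajectories[0].dt

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.trajectories])


def read_trajectories(path, column_map=None, group_by=None, delimiter=","):
    """Read a delimited trajectory table into :class:`TrajectoryGroup` objects.

    The table must provide columns for the track id, time (or frame), x and y.
    Rows are grouped by track id and sorted by time; ``dt`` is inferred as the
    modal inter-frame interval of the file. Tracks with fewer than 2 rows are
    dropped (count logged). A track whose intervals deviate from uniform by
    more than ``DT_TOLERANCE`` seconds raises a validation error naming it.

    Parameters
    ----------
    path : str or file-like
        Delimited text file.
    column_map : dict, optional
        Maps the canonical names ``track_id, t, x, y`` (or ``frame`` instead
        of ``t``) to the file's column names.
    group_by : str or list of str, optional
        Column(s) whose values partition the tracks into groups. When absent,
        a single group labelled ``None`` is returned.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, delimiter=delimiter)

    missing = [cmap[k] for k in ("track_id", "x", "y") if cmap[k] not in df.columns]
    has_t = cmap.get("t") in df.columns
    has_frame = cmap.get("frame", "frame") in df.columns
    if not (has_t or has_frame):
        missing.append(cmap.get("t", "t"))
    if missing:
        raise TrajectoryFormatError(f"missing mandatory column(s): {missing}")

    meta_cols = [
        c
        for c in df.columns
        if c not in {cmap["track_id"], cmap.get("t"), cmap.get("frame", "frame"),
                     cmap["x"], cmap["y"]}
    ]

    # time axis: explicit t column preferred, else the frame index (dt then
    # in frame units unless the file also encodes real time).
    tcol = cmap["t"] if has_t else cmap.get("frame", "frame")

    # modal inter-frame interval across all tracks defines dt
    df = df.sort_values([cmap["track_id"], tcol], kind="stable").reset_index(drop=True)
    diffs = []
    for _, sub in df.groupby(cmap["track_id"], sort=False):
        tv = sub[tcol].to_numpy(dtype=float)
        if len(tv) > 1:
            diffs.append(np.diff(tv))
    if not diffs:
        raise TrajectoryValidationError("no track has 2 or more rows")
    diffs = np.concatenate(diffs)
    vals, counts = np.unique(np.round(diffs, 9), return_counts=True)
    dt = float(vals[np.argmax(counts)])
    if dt <= 0:
        raise TrajectoryValidationError("inferred dt is not positive")

    groups: dict = {}
    n_dropped = 0
    group_cols = [group_by] if isinstance(group_by, str) else (group_by or [])
    for tid, sub in df.groupby(cmap["track_id"], sort=False):
        if len(sub) < 2:
            n_dropped += 1
            continue
        tv = sub[tcol].to_numpy(dtype=float)
        if np.any(np.abs(np.diff(tv) - dt) > DT_TOLERANCE):
            raise TrajectoryValidationError(
                f"track {tid}: non-uniform time lapse (tolerance {DT_TOLERANCE} s)"
            )
        pos = sub[[cmap["x"], cmap["y"]]].to_numpy(dtype=float)
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        traj = Trajectory(pos, dt=dt, track_id=tid, meta=meta)
        if group_cols:
            key = tuple(meta.get(c) for c in group_cols)
            if len(key) == 1:
                key = key[0]
        else:
            key = None
        groups.setdefault(key, []).append(traj)

    if n_dropped:
        logger.warning("dropped %d track(s) with fewer than 2 localizations", n_dropped)
    return [TrajectoryGroup(trajs, label=key) for key, trajs in groups.items()]


def write_trajectories(groups, path, delimiter=","):
    """Write trajectory groups back to the delimited-text table format.

    Inverse of :func:`read_trajectories`; positions round-trip to full float
    precision and per-trajectory ``meta`` entries become columns.
    """
    if isinstance(groups, TrajectoryGroup):
        groups = [groups]
    rows = []
    for g in groups:
        for traj in g:
            for i, (x, y) in enumerate(traj.positions):
                row = {
                    "track_id": traj.track_id,
                    "frame": i,
                    "t": i * traj.dt,
                    "x": x,
                    "y": y,
                }
                row.update(traj.meta)
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, float_format="%.12g")
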