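"""Sub-cellular region extraction and trajectory-to-region assignment.

Dense regions (e.g. synaptic boutons) are delimited from pooled localizations
by a Gaussian kernel density estimate thresholded at a fraction of its
maximum (defaults: 150 nm bandwidth, one tenth of the maximum). A trajectory
belongs to a region iff a strict majority of its localizations falls inside
that region's polygon; ties and split trajectories count as outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage import measure
from sklearn.neighbors import KernelDensity

from .trajectory import TrajectoryGroup

logger = logging.getLogger(__name__)


@dataclass
class RegionMask:
    """Named polygonal regions in the trajectory coordinate frame (um)."""

    regions: list  # list of (region_id, (M, 2) vertex array)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        cleaned = []
        for rid, verts in self.regions:
            verts = np.asarray(verts, dtype=float)
            poly = Polygon(verts)
            if not poly.is_valid:
                raise ValueError(f"region {rid!r}: polygon is not simple")
            cleaned.append((rid, verts))
        self.regions = cleaned

    def __len__(self) -> int:
        return len(self.regions)

    def polygons(self):
        return [(rid, Polygon(verts)) for rid, verts in self.regions]

    @classmethod
    def from_csv(cls, path, delimiter=","):
        """Load regions from a (region_id, vertex_x, vertex_y) table."""
        df = pd.read_csv(path, delimiter=delimiter)
        regions = [
            (rid, sub[["vertex_x", "vertex_y"]].to_numpy(dtype=float))
            for rid, sub in df.groupby("region_id", sort=False)
        ]
        return cls(regions)

    def to_csv(self, path, delimiter=","):
        rows = []
        for rid, verts in self.regions:
            for x, y in verts:
                rows.append({"region_id": rid, "vertex_x": x, "vertex_y": y})
        pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def assign_regions(group: TrajectoryGroup, mask: RegionMask):
    """Split a group into (inside, outside) by majority localization.

    A trajectory is inside region ``r`` iff strictly more than half of its
    localizations fall within ``r``'s polygon; it then gains
    ``meta['region_id'] = r``. All other trajectories (including exact ties
    and trajectories split across regions) are outside. Returns
    ``(inside_group_or_None, outside_group_or_None)``; empty partitions are
    returned as ``None``.
    """
    if mask is None or len(mask) == 0:
        logger.warning("empty region mask: all trajectories assigned outside")
        return None, TrajectoryGroup(list(group), label=(group.label, "outside"))

    prepared = [(rid, prep(poly)) for rid, poly in mask.polygons()]
    inside, outside = [], []
    for traj in group:
        n = len(traj)
        best = None
        for rid, ppoly in prepared:
            count = sum(ppoly.contains(Point(x, y)) for x, y in traj.positions)
            if count * 2 > n:  # strict majority
                best = rid
                break
        if best is not None:
            traj = type(traj)(
                traj.positions,
                dt=traj.dt,
                track_id=traj.track_id,
                meta={**traj.meta, "region_id": best},
            )
            inside.append(traj)
        else:
            outside.append(traj)
    inside_g = TrajectoryGroup(inside, label=(group.label, "inside")) if inside else None
    outside_g = TrajectoryGroup(outside, label=(group.label, "outside")) if outside else None
    return inside_g, outside_g


def extract_dense_regions(
    localizations,
    bandwidth: float = 0.150,
    threshold_frac: float = 0.1,
) -> RegionMask:
    """Delimit dense regions by thresholded Gaussian kernel density.

    The density of the pooled localizations is estimated on a regular grid
    (cell size ``bandwidth / 3``) with a Gaussian kernel of the given
    ``bandwidth`` (um); regions are the connected components of
    ``{density >= threshold_frac * max density}``, returned as contour
    polygons.
    """
    pts = np.asarray(localizations, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 localizations")
    if bandwidth <= 0 or not (0 < threshold_frac < 1):
        raise ValueError("bandwidth must be > 0 and threshold_frac in (0, 1)")
    span = pts.max(axis=0) - pts.min(axis=0)
    if np.all(span == 0):
        raise ValueError("all localizations identical: degenerate density")

    cell = bandwidth / 3.0
    pad = 3.0 * bandwidth
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    xs = np.arange(x0, x1 + cell, cell)
    ys = np.arange(y0, y1 + cell, cell)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    kde = KernelDensity(bandwidth=bandwidth, kernel="gaussian").fit(pts)
    dens = np.exp(kde.score_samples(grid)).reshape(gx.shape)

    level = threshold_frac * dens.max()
    regions = []
    for contour in measure.find_contours(dens, level):
        # contour in fractional grid indices -> um coordinates
        verts = np.column_stack(
            [x0 + contour[:, 0] * cell, y0 + contour[:, 1] * cell]
        )
        if len(verts) < 4:
            continue
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            continue
        regions.append((f"region_{len(regions)}", verts))
    if not regions:
        raise ValueError("no region exceeds the density threshold")
    # find_contours can return nested/duplicate contours when components touch
    # the grid border; keep only outermost ones
    polys = [(rid, Polygon(v)) for rid, v in regions]
    keep = []
    for i, (rid, poly) in enumerate(polys):
        if not any(j != i and other.contains(poly) for j, (_, other) in enumerate(polys)):
            keep.append(regions[i])
    return RegionMask(keep)
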