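"""Elastic-sphere centerline tracing through a segmented lumen.

The interactive "virtual elastic sphere" measurement — a sphere that inflates
against the lumen wall and slides from a start to an end seed — is realized
as a radius-weighted geodesic: on the 26-neighbor voxel graph of the mask,
each step costs its Euclidean length divided by the local inscribed-sphere
radius (the Euclidean distance-map value), so the optimal path hugs the
medial axis where the sphere is largest.  The per-point diameter is twice the
distance-map radius along the path.

Edge weights use the mean of the two endpoint inverse radii, making the cost
symmetric: tracing end-to-start returns the exact reversal of start-to-end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .volume import SegmentationMask

__all__ = ["CenterlinePath", "distance_map", "trace", "diameter_profile", "NearOcclusionWarning"]


class NearOcclusionWarning(UserWarning):
    """The optimal path squeezes through a gap under one voxel in radius."""


@dataclass
class CenterlinePath:
    """An ordered lumen path with per-point inscribed-sphere radius."""

    points: np.ndarray              # (n, 3) world mm
    radius: np.ndarray              # (n,) mm
    cumulative_arc_length: np.ndarray  # (n,) mm, non-decreasing, starts at 0
    cost: float = 0.0               # sum of step_length / radius along the voxel path
    voxel_indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.cumulative_arc_length = np.asarray(self.cumulative_arc_length, dtype=float)
        if not (len(self.points) == len(self.radius) == len(self.cumulative_arc_length)):
            raise ValueError("points, radius and arc length must have equal length")
        if np.any(np.diff(self.cumulative_arc_length) < 0):
            raise ValueError("arc length must be non-decreasing")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")

    @property
    def length(self) -> float:
        return float(self.cumulative_arc_length[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.points)),
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "radius_mm": self.radius,
                "arc_mm": self.cumulative_arc_length,
            }
        )


def distance_map(mask: SegmentationMask | np.ndarray, spacing=None) -> np.ndarray:
    """Anisotropy-aware Euclidean distance to the nearest background voxel (mm).

    Zero outside the mask.  A lone foreground voxel with isotropic spacing s
    has distance s (to the neighbouring background voxel centre).
    """
    if isinstance(mask, SegmentationMask):
        grid, spacing = mask.mask, mask.spacing
    else:
        grid = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required when mask is a bare array")
    if not grid.any():
        raise ValueError("mask is empty")
    return ndimage.distance_transform_edt(grid, sampling=spacing)


_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1) if (dx, dy, dz) > (0, 0, 0)],
    dtype=int,
)


def _snap_to_mask(grid: np.ndarray, spacing: np.ndarray, origin: np.ndarray, point_mm, ball_vox: int = 5):
    """Nearest mask voxel (by world distance) within a 5-voxel ball."""
    idx = np.rint((np.asarray(point_mm, dtype=float) - origin) / spacing).astype(int)
    lo = np.maximum(idx - ball_vox, 0)
    hi = np.minimum(idx + ball_vox + 1, np.asarray(grid.shape))
    window = grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    cand = np.argwhere(window) + lo
    if len(cand) == 0:
        raise ValueError(
            f"no mask voxel within {ball_vox} voxels of seed point {tuple(point_mm)}"
        )
    d2 = (((cand - (np.asarray(point_mm) - origin) / spacing) * spacing) ** 2).sum(axis=1)
    return tuple(int(v) for v in cand[int(np.argmin(d2))])


def trace(mask: SegmentationMask, start, end) -> CenterlinePath:
    """Radius-weighted shortest path between two seeds inside the mask.

    Seeds are world coordinates in mm; each snaps to the nearest mask voxel
    within a 5-voxel ball.  The returned path minimizes the sum of step
    length over local inscribed-sphere radius among all 26-connected voxel
    paths, then is smoothed with a 3-point moving average (endpoints fixed).

    Raises ``ValueError`` when the snapped seeds lie in different connected
    components; warns (:class:`NearOcclusionWarning`) when the optimal path
    passes a point with radius under one voxel.
    """
    grid = mask.mask
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    s_idx = _snap_to_mask(grid, spacing, origin, start)
    e_idx = _snap_to_mask(grid, spacing, origin, end)

    labels, _ = ndimage.label(grid, structure=np.ones((3, 3, 3), dtype=bool))
    if labels[s_idx] != labels[e_idx]:
        raise ValueError(
            f"seeds snap to different connected components ({labels[s_idx]} vs "
            f"{labels[e_idx]}): the lumen is broken between them"
        )

    radius = distance_map(grid, spacing)

    reversed_out = s_idx > e_idx  # canonical order => exact reversal symmetry
    a_idx, b_idx = (e_idx, s_idx) if reversed_out else (s_idx, e_idx)

    if a_idx == b_idx:
        pt = origin + np.asarray(a_idx) * spacing
        path_idx = np.asarray([a_idx])
        out = CenterlinePath(
            points=pt[None, :],
            radius=np.array([radius[a_idx]]),
            cumulative_arc_length=np.array([0.0]),
            cost=0.0,
            voxel_indices=path_idx,
        )
        return out

    comp = labels == labels[a_idx]
    node_id = np.full(grid.shape, -1, dtype=np.int64)
    coords = np.argwhere(comp)
    node_id[comp] = np.arange(len(coords))
    inv_r = 1.0 / radius[tuple(coords.T)]

    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        src_sl = tuple(slice(max(-o, 0), n - max(o, 0)) for o, n in zip(off, grid.shape))
        dst_sl = tuple(slice(max(o, 0), n - max(-o, 0)) for o, n in zip(off, grid.shape))
        u = node_id[src_sl]
        v = node_id[dst_sl]
        ok = (u >= 0) & (v >= 0)
        if not ok.any():
            continue
        step = float(np.linalg.norm(off * spacing))
        uu, vv = u[ok], v[ok]
        rows.append(uu)
        cols.append(vv)
        weights.append(step * 0.5 * (inv_r[uu] + inv_r[vv]))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    ).tocsr()

    a_node, b_node = int(node_id[a_idx]), int(node_id[b_idx])
    dist, pred = dijkstra(
        graph, directed=False, indices=a_node, return_predecessors=True
    )
    if not np.isfinite(dist[b_node]):
        raise RuntimeError("no path found despite common component")  # pragma: no cover

    chain = [b_node]
    while chain[-1] != a_node:
        chain.append(int(pred[chain[-1]]))
    chain = chain[::-1]
    path_idx = coords[chain]
    if reversed_out:
        path_idx = path_idx[::-1]

    # a minimal-spacing radius means the sphere has collapsed to one voxel
    path_r = radius[tuple(path_idx.T)]
    if path_r.min() <= spacing.min() * (1 + 1e-9):
        warnings.warn(
            f"path radius drops to {path_r.min():.4g} mm (< 1 voxel): "
            "near-occlusion along the trace",
            NearOcclusionWarning,
            stacklevel=2,
        )

    pts = origin + path_idx * spacing
    smoothed = pts.copy()
    if len(pts) > 2:
        smoothed[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(smoothed, axis=0), axis=1))])
    return CenterlinePath(
        points=smoothed,
        radius=path_r,
        cumulative_arc_length=arc,
        cost=float(dist[b_node]),
        voxel_indices=path_idx,
    )


def diameter_profile(path: CenterlinePath) -> pd.DataFrame:
    """Per-point luminal diameter (mm) against cumulative arc length (mm)."""
    return pd.DataFrame(
        {"arc_mm": path.cumulative_arc_length, "diameter_mm": 2.0 * path.radius}
    )
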