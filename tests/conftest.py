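"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass

import lumenprof as lp


# ---------------------------------------------------------------------------
# phantom helpers


@pytest.fixture
def straight_vessel():
    """A straight axial vessel, diameter 18 voxels at 18 um."""
    return lp.VesselSpec(
        [[0.0, 0.0, 0.0], [0.0, 0.0, 2.4]], base_diameter=0.324, length=2.4
    )


@pytest.fixture
def clean_scene(straight_vessel):
    """Noise-free, blur-free scene with muscle barely above background.

    With muscle ~ background the blood/muscle midpoint threshold sits at the
    half-occupancy isosurface, isolating voxelization fidelity from
    threshold-placement bias.
    """
    return lp.SceneSpec(
        [straight_vessel],
        intensity_blood=150.0,
        intensity_muscle=51.0,
        intensity_background=50.0,
        psf_sigma=0.0,
        noise_sd=0.0,
        rng_seed=0,
    )


def make_curved_scene(rng, diameter_vox, voxel=0.018, length=2.4, stenosis=None):
    """Curved single-vessel in vivo-like scene for recovery experiments."""
    lat = rng.uniform(-0.1, 0.1, size=(2, 2))
    v = lp.VesselSpec(
        [
            [0.0, 0.0, 0.0],
            [lat[0, 0], lat[0, 1], length / 3],
            [lat[1, 0], lat[1, 1], 2 * length / 3],
            [0.0, 0.0, length],
        ],
        base_diameter=diameter_vox * voxel,
        stenoses=[stenosis] if stenosis else [],
        length=length,
    )
    return lp.SceneSpec.in_vivo([v], voxel_size=voxel, rng_seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# random connected masks and the exhaustive path-cost oracle


def random_connected_mask(rng, shape=(8, 8, 8), density=0.55):
    """Largest 26-connected component of a smoothed random field."""
    field = ndimage.gaussian_filter(rng.random(shape), sigma=0.8)
    mask = field > np.quantile(field, 1 - density)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:  # pragma: no cover
        return random_connected_mask(rng, shape, density)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def bruteforce_path_cost(mask, spacing, start_idx, end_idx):
    """Optimal radius-weighted path cost by exhaustive relaxation.

    Independent of the production tracer: neighbours are enumerated by a
    double loop over voxel pairs and costs are relaxed Bellman-Ford style
    until a fixed point, which on a finite graph with positive weights is
    the global optimum.
    """
    spacing = np.asarray(spacing, dtype=float)
    radius = ndimage.distance_transform_edt(mask, sampling=spacing)
    coords = [tuple(c) for c in np.argwhere(mask)]
    index = {c: i for i, c in enumerate(coords)}
    edges = []
    for i, a in enumerate(coords):
        for j, b in enumerate(coords):
            if i < j and max(abs(a[k] - b[k]) for k in range(3)) == 1:
                step = float(np.linalg.norm((np.array(a) - np.array(b)) * spacing))
                w = step * 0.5 * (1.0 / radius[a] + 1.0 / radius[b])
                edges.append((i, j, w))
    dist = np.full(len(coords), np.inf)
    dist[index[tuple(start_idx)]] = 0.0
    changed = True
    while changed:
        changed = False
        for i, j, w in edges:
            if dist[i] + w < dist[j] - 1e-15:
                dist[j] = dist[i] + w
                changed = True
            if dist[j] + w < dist[i] - 1e-15:
                dist[i] = dist[j] + w
                changed = True
    return float(dist[index[tuple(end_idx)]])


def farthest_pair(mask):
    """Two mask voxels far apart (deterministic): lexicographic extremes."""
    coords = np.argwhere(mask)
    order = np.lexsort(coords.T[::-1])
    return tuple(coords[order[0]]), tuple(coords[order[-1]])
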