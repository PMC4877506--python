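"""Polyline geometry on labelled voxel grids.

All public functions work in world millimetres (RAS+). A voxel grid is
described by its 4x4 voxel-to-world affine; voxel ``i`` owns the half-open
interval ``[i - 0.5, i + 0.5)`` of continuous voxel coordinates along each
axis (nearest-voxel rule), so a world point maps to exactly one voxel.

The central primitive is :func:`traverse_voxels`, an exact plane-crossing
voxel walk: for every segment of a polyline it enumerates the crossings of
inter-voxel boundary planes and evaluates the segment at the midpoint of
each sub-interval, which yields *every* voxel whose ownership cell the
segment intersects — including thin corner clips that fixed-step sampling
misses. Fixed-step sampling remains available (``step=``) and is used as an
independent cross-check in the test-suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polyline_length",
    "resample_polyline",
    "world_to_voxel",
    "voxel_to_world",
    "nearest_voxel",
    "traverse_voxels",
    "traverse_voxels_batch",
    "sample_polyline_points",
]


def polyline_length(points: np.ndarray) -> float:
    """Total Euclidean length (mm) of an ordered point sequence."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) fixed arc-length steps.

    The first and last points are preserved exactly; interior samples are
    placed every ``step`` mm along the cumulative arc length.
    """
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return points[[0, -1]].copy()
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, points[:, d])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel coordinates."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(indices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map voxel indices (centres) to world mm."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    return indices @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def nearest_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Integer voxel index owning each world point (nearest-voxel rule)."""
    v = world_to_voxel(points, affine)
    return np.floor(v + 0.5).astype(np.int64)


def sample_polyline_points(points: np.ndarray, step: float) -> np.ndarray:
    """Dense fixed-step samples along a polyline, vertices included."""
    points = np.asarray(points, dtype=float)
    a, b = points[:-1], points[1:]
    seg = np.linalg.norm(b - a, axis=1)
    nsub = np.maximum(np.ceil(seg / step).astype(int), 1)
    chunks = [points[:1]]
    for i in range(len(seg)):
        t = np.linspace(0.0, 1.0, nsub[i] + 1)[1:, None]
        chunks.append(a[i] + t * (b[i] - a[i]))
    return np.vstack(chunks)


def _segment_crossings(a: np.ndarray, b: np.ndarray):
    """Boundary-crossing parameters for a batch of segments.

    ``a``/``b`` are (S, 3) segment endpoints in *shifted* voxel coordinates
    ``u = v + 0.5`` where ownership cells are ``[m, m+1)`` and boundaries sit
    at integers. Returns per-crossing segment ids and parameters t in (0, 1].
    """
    seg_ids = []
    ts = []
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    for d in range(3):
        k_lo = np.floor(lo[:, d]).astype(np.int64) + 1
        k_hi = np.floor(hi[:, d]).astype(np.int64)
        cnt = np.maximum(k_hi - k_lo + 1, 0)
        if cnt.sum() == 0:
            continue
        idx = np.repeat(np.arange(len(cnt)), cnt)
        start = np.cumsum(cnt) - cnt
        offset = np.arange(cnt.sum()) - np.repeat(start, cnt)
        k = np.repeat(k_lo, cnt) + offset
        denom = b[idx, d] - a[idx, d]
        t = (k - a[idx, d]) / denom
        seg_ids.append(idx)
        ts.append(t)
    if not seg_ids:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(seg_ids), np.concatenate(ts)


def traverse_voxels(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Exact set of voxel indices intersected by one polyline.

    Returns a (M, 3) int array of unique voxel indices (unbounded — callers
    clip or treat out-of-grid indices as background).
    """
    points = np.asarray(points, dtype=float)
    u = world_to_voxel(points, affine) + 0.5
    vox, _ = _walk_voxels_pairs(
        u[:-1], u[1:], np.zeros(len(u) - 1, dtype=np.int64)
    )
    return np.unique(vox, axis=0)


def traverse_voxels_batch(streamlines, affine: np.ndarray):
    """Exact voxel traversal for many polylines at once.

    Parameters
    ----------
    streamlines : sequence of (n_i, 3) arrays, world mm
    affine : 4x4 voxel-to-world map

    Returns
    -------
    vox : (M, 3) int array of traversed voxel indices
    owner : (M,) int array mapping each row to its streamline index

    Rows are unique per (streamline, voxel).
    """
    if len(streamlines) == 0:
        return np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.int64)
    lengths = np.array([len(s) for s in streamlines])
    pts = np.vstack([np.asarray(s, dtype=float) for s in streamlines])
    u = world_to_voxel(pts, affine) + 0.5
    owner_pt = np.repeat(np.arange(len(streamlines)), lengths)
    # segments joining consecutive points of the *same* streamline
    keep = owner_pt[1:] == owner_pt[:-1]
    a = u[:-1][keep]
    b = u[1:][keep]
    seg_owner = owner_pt[:-1][keep]
    vox, own = _walk_voxels_pairs(a, b, seg_owner)
    key = np.concatenate([own[:, None], vox], axis=1)
    key = np.unique(key, axis=0)
    return key[:, 1:], key[:, 0]


def _walk_voxels_pairs(a, b, seg_owner):
    cross_seg, cross_t = _segment_crossings(a, b)
    n_seg = len(a)
    base_seg = np.concatenate([np.arange(n_seg), np.arange(n_seg), cross_seg])
    base_t = np.concatenate([np.zeros(n_seg), np.ones(n_seg), cross_t])
    order = np.lexsort((base_t, base_seg))
    s = base_seg[order]
    t = base_t[order]
    same = s[1:] == s[:-1]
    mid_t = 0.5 * (t[1:] + t[:-1])[same]
    mid_s = s[1:][same]
    pts = a[mid_s] + mid_t[:, None] * (b[mid_s] - a[mid_s])
    vox = np.floor(pts).astype(np.int64)
    return vox, seg_owner[mid_s]
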