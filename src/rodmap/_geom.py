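"""Polyline geometry helpers used by segmentation and profiling.

Coordinates follow the numpy image convention (row, col), in pixel units
unless a function says otherwise.
"""

from __future__ import annotations

import numpy as np


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    """Total arc length of a polyline given as an (N, 2) array."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """Resample a polyline at `n` points evenly spaced by arc length.

    For closed polylines the duplicate endpoint is not repeated: the n
    samples cover [0, perimeter) at spacing perimeter/n.
    """
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    s = cumulative_arclength(pts)
    total = s[-1]
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    if closed:
        target = np.linspace(0.0, total, n, endpoint=False)
    else:
        target = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, pts[:, 0])
    out[:, 1] = np.interp(target, s, pts[:, 1])
    return out


def project_points_onto_polyline(
    points: np.ndarray, poly: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of points onto an open polyline.

    Returns (arclength, distance) per point: the arc-length coordinate of
    the nearest point on the polyline and the Euclidean distance to it.
    Vectorized over both points and segments (fine for the per-cell sizes
    this package handles).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    a = poly[:-1]                       # (S, 2) segment starts
    d = poly[1:] - a                    # (S, 2) segment vectors
    seg_len2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-30)
    # t[p, s]: projection parameter of point p on segment s, clipped to [0, 1]
    diff = p[:, None, :] - a[None, :, :]            # (P, S, 2)
    t = np.clip(np.einsum("psj,sj->ps", diff, d) / seg_len2, 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = np.sum((p[:, None, :] - foot) ** 2, axis=2)
    best = np.argmin(dist2, axis=1)
    idx = np.arange(len(p))
    s0 = cumulative_arclength(poly)[:-1]
    seg_len = np.sqrt(seg_len2)
    arclength = s0[best] + t[idx, best] * seg_len[best]
    return arclength, np.sqrt(dist2[idx, best])


def segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2D segments (scalar)."""
    p1, p2, q1, q2 = (np.asarray(x, dtype=float) for x in (p1, p2, q1, q2))

    def point_seg(pt, a, b):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            return float(np.hypot(*(pt - a)))
        t = np.clip(float((pt - a) @ ab) / denom, 0.0, 1.0)
        return float(np.hypot(*(pt - (a + t * ab))))

    if _segments_intersect(p1, p2, q1, q2):
        return 0.0
    return min(
        point_seg(p1, q1, q2),
        point_seg(p2, q1, q2),
        point_seg(q1, p1, p2),
        point_seg(q2, p1, p2),
    )


def _segments_intersect(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def window_overlap_weights(
    n_bins: int, length: float, lo: float, hi: float
) -> np.ndarray:
    """Fractional overlap of each of `n_bins` equal bins on [0, length]
    with the interval [lo, hi], as a fraction of each bin's width.

    Used for pro-rata integration of binned axial profiles over windows
    that do not align with bin edges.
    """
    edges = np.linspace(0.0, length, n_bins + 1)
    width = length / n_bins
    overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    return np.clip(overlap, 0.0, None) / width
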