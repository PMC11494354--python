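"""Low-level planar geometry kernels (vectorized numpy)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "segments_cross",
    "segment_pairs_cross",
    "ray_segment_intersections",
    "circle_exit_distance",
    "polygon_signed_area",
]


def segments_cross(p1, p2, q1, q2, eps: float = 1e-12) -> np.ndarray:
    """Proper-crossing test between segment (p1,p2) and segments (q1,q2).

    Broadcasts: p1,p2 shape (2,) against q1,q2 shape (n,2).  Shared endpoints
    (touching within eps) do not count as crossings.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    q1 = np.atleast_2d(np.asarray(q1, float))
    q2 = np.atleast_2d(np.asarray(q2, float))
    r = p2 - p1
    s = q2 - q1
    denom = r[0] * s[:, 1] - r[1] * s[:, 0]
    dq = q1 - p1
    t_num = dq[:, 0] * s[:, 1] - dq[:, 1] * s[:, 0]
    u_num = dq[:, 0] * r[1] - dq[:, 1] * r[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t_num / denom
        u = u_num / denom
    ok = np.abs(denom) > eps
    return ok & (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)


def segment_pairs_cross(a1, a2, b1, b2, eps: float = 1e-12) -> np.ndarray:
    """Elementwise proper-crossing test for paired segment arrays (n,2) each."""
    a1, a2, b1, b2 = (np.atleast_2d(np.asarray(x, float)) for x in (a1, a2, b1, b2))
    r = a2 - a1
    s = b2 - b1
    denom = r[:, 0] * s[:, 1] - r[:, 1] * s[:, 0]
    dq = b1 - a1
    t_num = dq[:, 0] * s[:, 1] - dq[:, 1] * s[:, 0]
    u_num = dq[:, 0] * r[:, 1] - dq[:, 1] * r[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t_num / denom
        u = u_num / denom
    ok = np.abs(denom) > eps
    return ok & (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)


def ray_segment_intersections(origin, direction, q1, q2, eps: float = 1e-9):
    """Intersections of ray origin + t*direction (t>eps) with segments (q1,q2).

    Returns (t, s): ray parameter and segment parameter arrays with np.inf / nan
    where there is no intersection.  Endpoint grazing within eps of a segment end
    still reports an intersection (s clamped by the caller if needed).
    """
    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    q1 = np.atleast_2d(np.asarray(q1, float))
    q2 = np.atleast_2d(np.asarray(q2, float))
    s_vec = q2 - q1
    denom = d[0] * s_vec[:, 1] - d[1] * s_vec[:, 0]
    dq = q1 - origin
    t_num = dq[:, 0] * s_vec[:, 1] - dq[:, 1] * s_vec[:, 0]
    u_num = dq[:, 0] * d[1] - dq[:, 1] * d[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t_num / denom
        u = u_num / denom
    bad = (np.abs(denom) <= 1e-14) | (t <= eps) | (u < -1e-9) | (u > 1 + 1e-9)
    t = np.where(bad, np.inf, t)
    return t, u


def circle_exit_distance(origin, direction, radius: float) -> float:
    """Distance along unit ray from origin (inside circle) to the circle."""
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    b = float(o @ d)
    c = float(o @ o) - radius * radius
    disc = b * b - c
    if disc < 0:
        return np.inf
    return -b + np.sqrt(disc)


def polygon_signed_area(xy: np.ndarray) -> float:
    """Shoelace signed area of vertex loop (n,2); positive = counterclockwise."""
    x = xy[:, 0]
    y = xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
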