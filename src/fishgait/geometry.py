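"""Shared planar-geometry primitives.

Conventions used across the package:

* Points are ``(x, y)`` in image coordinates: x to the right, y **down**,
  origin at the top-left corner of the (cropped) frame.
* Angles are reported as a viewer of the printed frame would read them:
  counter-clockwise positive. Because image y points down, this means
  ``angle = atan2(-dy, dx)``. All angles live in ``(-pi, pi]`` unless
  explicitly unwrapped.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_orientation",
    "wrap_angle",
    "arc_lengths",
    "resample_polyline",
    "polyline_length",
]


def segment_orientation(p, q) -> float:
    """Orientation of the vector p -> q, in rad, in (-pi, pi].

    Viewer convention (y axis flipped): counter-clockwise positive on the
    printed frame. Raises ``ValueError`` for coincident points, where the
    direction is undefined.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    if np.hypot(d[0], d[1]) == 0.0:
        raise ValueError("coincident points have no orientation")
    ang = float(np.arctan2(-d[1], d[0]))
    # atan2 returns [-pi, pi]; fold -pi onto +pi so the range is (-pi, pi]
    if ang == -np.pi:
        ang = np.pi
    return ang


def wrap_angle(delta):
    """Wrap an angle difference (rad) into (-pi, pi].

    Accepts scalars or arrays. ``wrap_angle(b - a)`` is the minimum-magnitude
    representative of the rotation taking direction ``a`` to direction ``b``.
    """
    wrapped = -np.remainder(-np.asarray(delta, dtype=float) + np.pi, 2 * np.pi) + np.pi
    if np.ndim(delta) == 0:
        return float(wrapped)
    return wrapped


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline of shape (m, 2); starts at 0."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_length(points: np.ndarray) -> float:
    return float(arc_lengths(points)[-1])


def resample_polyline(points: np.ndarray, fractions) -> np.ndarray:
    """Sample a polyline at the given fractions of its total arc length.

    ``fractions`` are in [0, 1]; returns an array of shape (len(fractions), 2).
    Degenerate (zero-length) polylines raise ``ValueError``.
    """
    pts = np.asarray(points, dtype=float)
    s = arc_lengths(pts)
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    targets = np.asarray(fractions, dtype=float) * total
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.column_stack([x, y])
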