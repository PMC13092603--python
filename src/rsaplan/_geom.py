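"""Small linear-algebra helpers used across the geometric modules.

All coordinates are millimetres in the canonical right-shoulder scapular
frame: origin at the glenoid center, +x lateral (along the Friedman line),
+y superior, +z anterior.
"""
from __future__ import annotations

import numpy as np

from .errors import GeometryError

X_LATERAL = np.array([1.0, 0.0, 0.0])
Y_SUPERIOR = np.array([0.0, 1.0, 0.0])
Z_ANTERIOR = np.array([0.0, 0.0, 1.0])


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize a near-zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def rotate_about_point(points: np.ndarray, R: np.ndarray, center: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = (pts - center) @ R.T + center
    return out[0] if np.asarray(points).ndim == 1 else out


def mirror_z(points: np.ndarray) -> np.ndarray:
    """Reflect across the scapular plane (z -> -z); the left/right mirror."""
    pts = np.asarray(points, dtype=float).copy()
    pts[..., 2] *= -1.0
    return pts
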