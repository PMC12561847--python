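"""Small planar-kinematics helpers used throughout the package.

Angles are radians, counterclockwise positive; lengths are millimetres.
"""

from __future__ import annotations

import numpy as np

#: 90-degree counterclockwise rotation (the planar "cross product" operator).
J = np.array([[0.0, -1.0], [1.0, 0.0]])


def unit(angle):
    """Unit vector(s) at direction ``angle`` (rad)."""
    angle = np.asarray(angle, dtype=float)
    return np.stack([np.cos(angle), np.sin(angle)], axis=-1)


def rot(angle: float) -> np.ndarray:
    """2x2 counterclockwise rotation matrix."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def wrap_pi(angle):
    """Reduce angle(s) to the interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if np.isscalar(angle) or out.ndim == 0 else out


def polyline_arc_length(points: np.ndarray) -> float:
    """Total arc length of an ordered (n, 2) polyline."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
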