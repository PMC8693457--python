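"""Shared frame conventions and angular <-> tangent-plane conversions.

Retinal frame: right-handed, z along the gaze direction, x rightward,
y upward; the image plane sits at focal distance f = 1, so an image point
(x, y) is the tangent-plane projection of the viewing ray (x, y, 1).

World frame: x rightward, y up (against gravity), z along the horizontal
projection of the gaze (the gaze azimuth).  The two frames differ by a single
rotation about the x axis by the gaze depression angle.

Visual-field degree coordinates are azimuthal-equidistant: a point at
eccentricity e (deg) in image-plane direction u (unit 2-vector) is written
e * u; patches are sampled and measured in this chart.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rot_x",
    "world_from_retinal_matrix",
    "retinal_from_world_matrix",
    "tangent_to_field_deg",
    "field_deg_to_tangent",
    "eccentricity_deg",
]


def rot_x(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def world_from_retinal_matrix(gaze_depression_deg: float) -> np.ndarray:
    """Rotation taking retinal-frame vectors to the world frame.

    Maps the gaze axis (0,0,1) to (0, -sin a, cos a): depressed by ``a`` below
    the horizontal.
    """
    return rot_x(np.radians(gaze_depression_deg))


def retinal_from_world_matrix(gaze_depression_deg: float) -> np.ndarray:
    return world_from_retinal_matrix(gaze_depression_deg).T


def tangent_to_field_deg(pts) -> np.ndarray:
    """Image-plane tangent coordinates -> azimuthal-equidistant degrees."""
    pts = np.asarray(pts, dtype=float)
    r = np.linalg.norm(pts, axis=-1)
    ecc = np.degrees(np.arctan(r))
    safe = np.where(r == 0, 1.0, r)
    return ecc[..., None] * pts / safe[..., None]


def field_deg_to_tangent(deg) -> np.ndarray:
    """Azimuthal-equidistant degrees -> image-plane tangent coordinates."""
    deg = np.asarray(deg, dtype=float)
    e = np.linalg.norm(deg, axis=-1)
    t = np.tan(np.radians(e))
    safe = np.where(e == 0, 1.0, e)
    return t[..., None] * deg / safe[..., None]


def eccentricity_deg(pts) -> np.ndarray:
    """Angular distance (deg) of image point(s) from the gaze direction."""
    pts = np.asarray(pts, dtype=float)
    return np.degrees(np.arctan(np.linalg.norm(pts, axis=-1)))
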