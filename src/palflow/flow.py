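"""Retinal optic flow for translation over a ground plane with gaze fixation.

The instantaneous flow of a static scene point P = (X, Y, Z) (retinal frame,
Z along gaze, focal distance f = 1) under observer translation T and eye
rotation Omega is

    v = (1/Z) * [[-1, 0, x], [0, -1, y]] @ T
        + [[x*y, -(1+x^2),  y],
           [1+y^2, -x*y,   -x]] @ Omega,        x = X/Z, y = Y/Z,

the time derivative of the perspective projection.  The scenario fixes gaze
on a ground point; the pursuit rotation Omega is solved so that the
undistorted flow vanishes exactly at the fixation point (image origin), with
no torsion about the line of sight.  A lens distortion F acts on the flow by
moving positions to F(p) and transporting velocities with the Jacobian,
v_d = J_F(p) @ v.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np

from .distortion import DistortionField
from .geometry import (
    eccentricity_deg,
    retinal_from_world_matrix,
    world_from_retinal_matrix,
)

__all__ = [
    "MotionScenario",
    "FlowField",
    "GeometryError",
    "ray_to_ground",
    "flow_vector",
    "solve_fixation_rotation",
    "distort_flow",
    "build_flow_field",
    "compare_flow_fields",
]


class GeometryError(ValueError):
    """Raised for rays or points with no valid ground-plane geometry."""


@dataclass(frozen=True)
class MotionScenario:
    """Observer translation over a ground plane while fixating a floor point.

    Defaults follow the study protocol: walking speed 2 m/s, eye height
    1.8 m, gaze depressed 20 deg onto the fixation point, heading offset
    laterally by +-20 deg (azimuth, about the vertical axis) from the gaze
    azimuth with a small vertical component (deg, relative to ground-
    parallel; positive = upward).
    """

    speed: float = 2.0
    heading_azimuth_world: float = 20.0
    heading_vertical_world: float = 0.0
    eye_height: float = 1.8
    gaze_depression: float = 20.0
    f: float = 1.0

    def __post_init__(self):
        if self.eye_height <= 0:
            raise ValueError("eye_height must be positive")
        if not 0 < self.gaze_depression < 90:
            raise ValueError("gaze_depression must lie in (0, 90) deg")

    @property
    def translation_world(self) -> np.ndarray:
        """T in the world frame (m/s)."""
        b = np.radians(self.heading_azimuth_world)
        v = np.radians(self.heading_vertical_world)
        return self.speed * np.array(
            [np.sin(b) * np.cos(v), np.sin(v), np.cos(b) * np.cos(v)])

    @property
    def translation_retinal(self) -> np.ndarray:
        return retinal_from_world_matrix(self.gaze_depression) @ self.translation_world

    @property
    def fixation_depth(self) -> float:
        """Distance along the gaze axis to the fixated ground point (m)."""
        return self.eye_height / np.sin(np.radians(self.gaze_depression))


def ray_to_ground(p, scenario: MotionScenario) -> Optional[np.ndarray]:
    """Intersect viewing ray(s) through image point(s) ``p`` with the ground.

    Returns the 3-D point(s) in the retinal frame (Z along gaze), or None
    (NaN rows for array input) where the ray never reaches the ground ahead
    of the observer.
    """
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    single = np.asarray(p).ndim == 1
    a = np.radians(scenario.gaze_depression)
    # World-vertical component of the (un-normalized) ray (x, y, 1).
    descent = np.sin(a) - pts[:, 1] * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = scenario.eye_height / descent
    valid = descent > 0
    out = np.where(valid[:, None],
                   t[:, None] * np.column_stack([pts[:, 0], pts[:, 1],
                                                 np.ones(len(pts))]),
                   np.nan)
    if single:
        return out[0] if valid[0] else None
    return out


def _flow_matrices(x: np.ndarray, y: np.ndarray):
    """Translation template A(p) (rows for T) and rotation matrix B(p), f=1."""
    n = len(x)
    a = np.zeros((n, 2, 3))
    a[:, 0, 0] = -1.0
    a[:, 0, 2] = x
    a[:, 1, 1] = -1.0
    a[:, 1, 2] = y
    b = np.empty((n, 2, 3))
    b[:, 0, 0] = x * y
    b[:, 0, 1] = -(1.0 + x * x)
    b[:, 0, 2] = y
    b[:, 1, 0] = 1.0 + y * y
    b[:, 1, 1] = -x * y
    b[:, 1, 2] = -x
    return a, b


def flow_vector(P, T, Omega) -> np.ndarray:
    """Instantaneous image velocity of scene point(s) ``P`` (retinal frame)."""
    pts = np.atleast_2d(np.asarray(P, dtype=float))
    single = np.asarray(P).ndim == 1
    Z = pts[:, 2]
    if np.any(Z <= 0):
        raise GeometryError("scene point behind the image plane (Z <= 0)")
    x, y = pts[:, 0] / Z, pts[:, 1] / Z
    a, b = _flow_matrices(x, y)
    v = (a @ np.asarray(T, dtype=float)) / Z[:, None] + b @ np.asarray(Omega, dtype=float)
    return v[0] if single else v


def solve_fixation_rotation(scenario: MotionScenario) -> np.ndarray:
    """Torsion-free pursuit rotation nulling the flow at the fixation point.

    At the image origin the translation term is -(T_X, T_Y)/Z_f and the
    rotation term (-Omega_Y, Omega_X); with Omega_Z = 0 the unique nulling
    rotation is Omega = (T_Y/Z_f, -T_X/Z_f, 0).
    """
    t = scenario.translation_retinal
    zf = scenario.fixation_depth
    return np.array([t[1] / zf, -t[0] / zf, 0.0])


def distort_flow(positions, velocities, field: DistortionField):
    """Apply a distortion field to flow: p -> F(p), v -> J_F(p) @ v."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    vel = np.atleast_2d(np.asarray(velocities, dtype=float))
    new_pos = np.atleast_2d(field(pos))
    jac = field.jacobian(pos)
    if jac.ndim == 2:
        jac = jac[None]
    new_vel = np.einsum("nij,nj->ni", jac, vel)
    if np.asarray(positions).ndim == 1:
        return new_pos[0], new_vel[0]
    return new_pos, new_vel


@dataclass
class FlowField:
    """Patched flow field for one scenario/condition.

    ``positions[k]``/``velocities[k]`` are the (N, 2) arrays for patch k.
    ``distortion`` is the applied field (None = undistorted); kept so dense
    re-evaluation (difference maps) can be done independently of the patches.
    """

    patches: Sequence
    positions: list
    velocities: list
    scenario: MotionScenario
    condition: str = "undistorted"
    fov_radius: float = 55.0
    distortion: Optional[DistortionField] = None

    def all_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.positions), np.concatenate(self.velocities)

    def to_frame(self):
        """Tabular view: one row per flow vector (patch id, x, y, vx, vy)."""
        import pandas as pd
        rows = []
        for k, (pos, vel) in enumerate(zip(self.positions, self.velocities)):
            for (x, y), (vx, vy) in zip(pos, vel):
                rows.append((k, x, y, vx, vy))
        return pd.DataFrame(rows, columns=["patch", "x", "y", "vx", "vy"])


def _undistorted_flow_at(points: np.ndarray, scenario: MotionScenario,
                         omega: np.ndarray) -> np.ndarray:
    ground = ray_to_ground(points, scenario)
    if np.any(~np.isfinite(np.atleast_2d(ground))):
        raise GeometryError("patch point with no ground intersection")
    return flow_vector(ground, scenario.translation_retinal, omega)


def build_flow_field(scenario: MotionScenario, patches: Sequence,
                     field: Optional[DistortionField] = None,
                     condition: Optional[str] = None,
                     fov_radius: float = 55.0) -> FlowField:
    """Compute the (possibly distorted) flow field over the given patches.

    The pursuit rotation is solved once in the undistorted geometry and
    reused unchanged under distortion; the distortion then acts purely on
    the image-plane flow via the Jacobian transport.
    """
    omega = solve_fixation_rotation(scenario)
    positions, velocities = [], []
    for patch in patches:
        pts = np.asarray(patch.points, dtype=float)
        vel = _undistorted_flow_at(pts, scenario, omega)
        if field is not None:
            pts, vel = distort_flow(pts, vel, field)
        positions.append(pts)
        velocities.append(vel)
    if condition is None:
        condition = "undistorted" if field is None else field.label
    return FlowField(list(patches), positions, velocities, scenario,
                     condition=condition, fov_radius=fov_radius,
                     distortion=field)


def compare_flow_fields(a: FlowField, b: FlowField, grid_points,
                        speed_floor: float = 1e-3):
    """Direction and speed difference maps between two flow conditions.

    Both fields are re-evaluated analytically on the dense lattice
    ``grid_points`` ((M, 2) tangent coordinates), independent of their
    patches.  Returns ``(angle_deg, ratio, mask)``: the signed angle (deg,
    anti-clockwise positive) from the a-vector to the b-vector, the speed
    ratio |v_b|/|v_a|, and a validity mask (False where the ground is not
    visible, a query left a distortion domain, or the reference speed falls
    below ``speed_floor``, where direction/ratio lose meaning).
    """
    if a.scenario != b.scenario:
        raise ValueError("flow fields must share a scenario")
    pts = np.atleast_2d(np.asarray(grid_points, dtype=float))
    scenario = a.scenario
    omega = solve_fixation_rotation(scenario)
    ground = ray_to_ground(pts, scenario)
    mask = np.all(np.isfinite(ground), axis=-1)
    angle = np.full(len(pts), np.nan)
    ratio = np.full(len(pts), np.nan)
    va = np.full((len(pts), 2), np.nan)
    vb = np.full((len(pts), 2), np.nan)
    idx = np.nonzero(mask)[0]
    if idx.size:
        vel = flow_vector(ground[idx], scenario.translation_retinal, omega)
        for out, ff in ((va, a), (vb, b)):
            if ff.distortion is None:
                out[idx] = vel
            else:
                inside = ff.distortion.contains(pts[idx])
                sub = idx[inside]
                if sub.size:
                    _, out[sub] = distort_flow(pts[sub], vel[inside], ff.distortion)
                mask[idx[~inside]] = False
    sa = np.linalg.norm(va, axis=-1)
    sb = np.linalg.norm(vb, axis=-1)
    mask &= np.isfinite(sa) & np.isfinite(sb) & (sa >= speed_floor)
    ok = mask
    cross = va[ok, 0] * vb[ok, 1] - va[ok, 1] * vb[ok, 0]
    dot = np.einsum("ij,ij->i", va[ok], vb[ok])
    angle[ok] = np.degrees(np.arctan2(cross, dot))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[ok] = sb[ok] / sa[ok]
    return angle, ratio, mask
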