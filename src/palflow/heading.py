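"""Patch-based subspace-algorithm heading estimation.

The estimator scores each candidate translation direction t by how much of
the observed flow cannot be explained by *any* combination of per-point
inverse depths and a torsion-free eye rotation.  For N flow vectors the
admissible flows form the column space of

    C(t) = [ A(p_1) t | ... | A(p_N) t | B_x | B_y ],       (2N x (N+2))

where A(p) t is the translation template at point p and B_x, B_y are the
rotation columns for Omega_X, Omega_Y (Omega_Z = 0, no torsion).  The
residual is the squared norm of the flow component orthogonal to that
subspace.  Because each translation column touches only one point's two
rows, the projection reduces exactly to: take, at every point, the scalar
component of the flow along the unit vector perpendicular to A(p) t, and
solve a small N x 2 least-squares problem over the rotation.  That reduction
is what is implemented (vectorized over candidate grids); tests check it
against the dense-matrix formulation.

The flow field is split into eccentricity-scaled patches, each patch yields
a residual surface over the candidate grid, and the heading estimate is the
argmin of the summed surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowField, MotionScenario
from .geometry import field_deg_to_tangent, retinal_from_world_matrix

__all__ = [
    "Patch",
    "HeadingGrid",
    "ResidualSurface",
    "HeadingEstimate",
    "EstimationError",
    "patch_area",
    "sample_patches",
    "subspace_residual",
    "residual_surface",
    "patch_residual_surfaces",
    "estimate_heading",
    "to_likelihood_map",
]

_PINV_RTOL = 1e-10  # relative rank tolerance for the 2x2 rotation solve


class EstimationError(RuntimeError):
    """Raised when no informative patch is available for estimation."""


def patch_area(eccentricity_deg_: float) -> float:
    """Patch area (deg^2) as a function of center eccentricity (deg).

    Receptive-field-like scaling: the patch diameter grows linearly with
    eccentricity, A = (1.04 + 0.61 * ecc)^2.
    """
    ecc = np.asarray(eccentricity_deg_, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be non-negative")
    out = (1.04 + 0.61 * ecc) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Patch:
    """Circular flow patch in azimuthal-equidistant visual-field coordinates."""

    center_deg: tuple[float, float]
    eccentricity: float          # deg, of the center
    area: float                  # deg^2
    radius: float                # deg, sqrt(area / pi)
    points: np.ndarray           # (n, 2) tangent-plane image points
    points_deg: np.ndarray       # (n, 2) visual-field degree coordinates

    @property
    def max_point_eccentricity(self) -> float:
        """Largest eccentricity among the patch's sample points (deg);
        a patch contributes at effective FoV radius r only if this is <= r."""
        return float(np.max(np.linalg.norm(self.points_deg, axis=-1)))


def _ground_visible(points_deg: np.ndarray, scenario: MotionScenario) -> np.ndarray:
    tangent = field_deg_to_tangent(points_deg)
    a = np.radians(scenario.gaze_depression)
    return np.sin(a) - tangent[..., 1] * np.cos(a) > 0


def sample_patches(fov_radius: float, n: int, scenario: MotionScenario,
                   seed, n_points: int = 10, max_draws: int = 100_000) -> list[Patch]:
    """Draw ``n`` random patches inside the FoV disc over visible ground.

    Centers are uniform over the part of the FoV disc (azimuthal-equidistant
    chart) whose viewing rays hit the ground; each patch gets the
    eccentricity-scaled area and ``n_points`` points uniform in its disc,
    rejection-sampled until every point is inside the FoV and on visible
    ground.  Deterministic for a given seed.
    """
    if fov_radius > 55 + 1e-9:
        raise ValueError("fov_radius must not exceed 55 deg")
    if n < 1:
        raise ValueError("need at least one patch")
    rng = np.random.default_rng(seed)
    patches = []
    draws = 0
    while len(patches) < n:
        draws += 1
        if draws > max_draws:
            raise EstimationError(
                "could not place patches: visible-ground region too small")
        r = fov_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        center = np.array([r * np.cos(phi), r * np.sin(phi)])
        if not _ground_visible(center, scenario):
            continue
        area = patch_area(r)
        radius = float(np.sqrt(area / np.pi))
        pts_deg = np.empty((n_points, 2))
        filled = 0
        for _ in range(max_draws):
            need = n_points - filled
            rr = radius * np.sqrt(rng.uniform(size=need))
            pp = rng.uniform(0, 2 * np.pi, size=need)
            cand = center + np.column_stack([rr * np.cos(pp), rr * np.sin(pp)])
            ok = (np.linalg.norm(cand, axis=-1) <= fov_radius) \
                & _ground_visible(cand, scenario)
            take = cand[ok]
            pts_deg[filled:filled + len(take)] = take
            filled += len(take)
            if filled == n_points:
                break
        else:
            raise EstimationError("could not fill a patch with valid points")
        patches.append(Patch(
            center_deg=(float(center[0]), float(center[1])),
            eccentricity=float(r), area=float(area), radius=radius,
            points=field_deg_to_tangent(pts_deg), points_deg=pts_deg))
    return patches


class HeadingGrid:
    """Rectangular grid of candidate translation directions.

    Coordinates are (azimuth, elevation) in degrees: azimuth about the
    world-vertical axis relative to the gaze azimuth, elevation relative to
    ground-parallel plus the gaze depression.  With gaze depressed 20 deg,
    the node (0, 20) is the translation parallel to the floor toward the
    fixation point, and a heading with lateral offset beta and vertical
    angle v sits exactly at node (beta, v + 20).  Each node maps to a unit
    3-D direction in the retinal frame.
    """

    def __init__(self, step: float = 0.25,
                 azimuth_center: float = 0.0, azimuth_span: float = 70.0,
                 elevation_center: float = 20.0, elevation_span: float = 20.0,
                 gaze_depression: float = 20.0):
        for span in (azimuth_span, elevation_span):
            if abs(round(span / step) - span / step) > 1e-9:
                raise ValueError("step must divide both spans")
        self.step = float(step)
        self.azimuth_center = float(azimuth_center)
        self.elevation_center = float(elevation_center)
        self.gaze_depression = float(gaze_depression)
        na = int(round(azimuth_span / step)) + 1
        ne = int(round(elevation_span / step)) + 1
        self.azimuths = azimuth_center + (np.arange(na) - (na - 1) / 2) * step
        self.elevations = elevation_center + (np.arange(ne) - (ne - 1) / 2) * step
        az, el = np.meshgrid(self.azimuths, self.elevations, indexing="ij")
        self.az_flat = az.ravel()
        self.el_flat = el.ravel()
        self.shape = (na, ne)
        self.directions = self._directions(self.az_flat, self.el_flat)

    def _directions(self, az_deg, el_deg) -> np.ndarray:
        a = np.radians(np.asarray(az_deg, dtype=float))
        ev = np.radians(np.asarray(el_deg, dtype=float) - self.gaze_depression)
        d_world = np.stack([np.sin(a) * np.cos(ev), np.sin(ev),
                            np.cos(a) * np.cos(ev)], axis=-1)
        return d_world @ retinal_from_world_matrix(self.gaze_depression).T

    def __len__(self) -> int:
        return len(self.az_flat)

    def node_index(self, azimuth: float, elevation: float) -> int:
        ia = int(round((azimuth - self.azimuths[0]) / self.step))
        ie = int(round((elevation - self.elevations[0]) / self.step))
        if not (0 <= ia < self.shape[0] and 0 <= ie < self.shape[1]
                and abs(self.azimuths[ia] - azimuth) < 1e-9
                and abs(self.elevations[ie] - elevation) < 1e-9):
            raise ValueError(f"({azimuth}, {elevation}) is not a grid node")
        return ia * self.shape[1] + ie


@dataclass
class ResidualSurface:
    """Least-squares residuals over the candidate grid (flat, az-major)."""

    grid: HeadingGrid
    values: np.ndarray
    n_vectors: int

    def as_array(self) -> np.ndarray:
        return self.values.reshape(self.grid.shape)

    def to_frame(self):
        """Tabular view for plotting: azimuth, elevation, residual per node."""
        import pandas as pd
        return pd.DataFrame({"azimuth": self.grid.az_flat,
                             "elevation": self.grid.el_flat,
                             "residual": self.values})


@dataclass(frozen=True)
class HeadingEstimate:
    azimuth: float               # deg, grid coordinate
    elevation: float             # deg, grid coordinate
    world_vertical: float        # deg relative to ground-parallel
    residual: float
    index: int
    n_patches: int
    n_ties: int = 1


def _batch_residuals(positions: np.ndarray, velocities: np.ndarray,
                     directions: np.ndarray) -> np.ndarray:
    """Subspace residuals of one vector set for a batch of candidates.

    positions/velocities: (N, 2); directions: (G, 3) unit vectors in the
    retinal frame.  Returns (G,) residuals.
    """
    if len(positions) <= 2:
        # 2N equations vs N+2 unknowns: the subspace is the whole space.
        return np.zeros(len(directions))
    x, y = positions[:, 0], positions[:, 1]
    vx, vy = velocities[:, 0], velocities[:, 1]
    t0 = directions[:, 0:1]
    t1 = directions[:, 1:2]
    t2 = directions[:, 2:3]
    # Translation template A(p) t at each point, for every candidate: (G, N).
    at_x = -t0 + x[None, :] * t2
    at_y = -t1 + y[None, :] * t2
    norm = np.hypot(at_x, at_y)
    safe = np.where(norm > 0, norm, 1.0)
    ux = -at_y / safe   # unit vector perpendicular to the template
    uy = at_x / safe
    d = ux * vx[None, :] + uy * vy[None, :]
    # Rotation columns projected on the same perpendicular directions.
    bx0, bx1 = x * y, -(1.0 + x * x)          # row-1 entries for Omega_X/Y
    by0, by1 = 1.0 + y * y, -x * y            # row-2 entries
    b1 = ux * bx0[None, :] + uy * by0[None, :]
    b2 = ux * bx1[None, :] + uy * by1[None, :]
    m11 = np.einsum("gn,gn->g", b1, b1)
    m12 = np.einsum("gn,gn->g", b1, b2)
    m22 = np.einsum("gn,gn->g", b2, b2)
    r1 = np.einsum("gn,gn->g", b1, d)
    r2 = np.einsum("gn,gn->g", b2, d)
    dd = np.einsum("gn,gn->g", d, d)
    det = m11 * m22 - m12 * m12
    scale = np.maximum(m11 * m22, 1e-300)
    good = det > _PINV_RTOL * scale
    res = np.empty(len(directions))
    with np.errstate(divide="ignore", invalid="ignore"):
        expl = (m22 * r1 * r1 - 2.0 * m12 * r1 * r2 + m11 * r2 * r2) / det
    res[good] = dd[good] - expl[good]
    # Rank-deficient rotation normal matrix: fall back to a dense solve.
    for g in np.nonzero(~good)[0]:
        bmat = np.column_stack([b1[g], b2[g]])
        sol, rss, rank, _ = np.linalg.lstsq(bmat, d[g], rcond=_PINV_RTOL)
        res[g] = dd[g] - np.dot(bmat @ sol, d[g])
    return np.maximum(res, 0.0)


def subspace_residual(positions, velocities, direction) -> float:
    """Least-squares residual of a flow-vector set for one candidate direction.

    Minimized over all per-point inverse depths and torsion-free rotations;
    zero means the candidate explains the flow perfectly.  With fewer than
    three vectors the unknowns outnumber the equations and the residual is
    identically zero (uninformative).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return float(_batch_residuals(positions, velocities, direction[None])[0])


def is_informative(n_vectors: int) -> bool:
    """Whether ``n_vectors`` flow vectors can constrain the candidate at all
    (2N equations must exceed the N + 2 unknowns, i.e. N >= 3)."""
    return n_vectors >= 3


def residual_surface(positions, velocities, grid: HeadingGrid) -> ResidualSurface:
    """Residual at every candidate-grid node for one set of flow vectors."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    values = _batch_residuals(positions, velocities, grid.directions)
    return ResidualSurface(grid, values, len(positions))


def patch_residual_surfaces(field: FlowField, grid: HeadingGrid) -> list[ResidualSurface]:
    """Per-patch residual surfaces (order matches ``field.patches``)."""
    return [residual_surface(pos, vel, grid)
            for pos, vel in zip(field.positions, field.velocities)]


def _argmin_with_ties(values: np.ndarray, grid: HeadingGrid) -> tuple[int, int]:
    best = values.min()
    ties = np.nonzero(values == best)[0]
    if len(ties) == 1:
        return int(ties[0]), 1
    dist = np.hypot(grid.az_flat[ties] - grid.azimuth_center,
                    grid.el_flat[ties] - grid.elevation_center)
    order = np.lexsort((grid.el_flat[ties], grid.az_flat[ties], dist))
    return int(ties[order[0]]), len(ties)


def estimate_heading(field: FlowField, grid: HeadingGrid,
                     fov_radius: float | None = None,
                     surfaces: list[ResidualSurface] | None = None
                     ) -> tuple[HeadingEstimate, ResidualSurface]:
    """Sum per-patch residual surfaces and return the argmin heading.

    Only patches whose points all lie within ``fov_radius`` (default: the
    field's own radius) and that carry enough vectors to be informative
    contribute.  Ties at the minimum are broken by distance to the grid
    center, then lexicographically by (azimuth, elevation).  Precomputed
    ``surfaces`` may be passed to re-estimate under different FoV radii
    without recomputation.
    """
    if fov_radius is None:
        fov_radius = field.fov_radius
    if surfaces is None:
        surfaces = patch_residual_surfaces(field, grid)
    total = np.zeros(len(grid))
    used = 0
    n_vec = 0
    for patch, surf in zip(field.patches, surfaces):
        if patch.max_point_eccentricity > fov_radius + 1e-9:
            continue
        if not is_informative(surf.n_vectors):
            continue
        total += surf.values
        used += 1
        n_vec += surf.n_vectors
    if used == 0:
        raise EstimationError(
            f"no informative patch inside FoV radius {fov_radius} deg")
    idx, ties = _argmin_with_ties(total, grid)
    est = HeadingEstimate(
        azimuth=float(grid.az_flat[idx]),
        elevation=float(grid.el_flat[idx]),
        world_vertical=float(grid.el_flat[idx] - grid.gaze_depression),
        residual=float(total[idx]), index=idx, n_patches=used, n_ties=ties)
    return est, ResidualSurface(grid, total, n_vec)


def to_likelihood_map(surface: ResidualSurface) -> np.ndarray:
    """Display transform: log-compress residuals and flip/normalize to [0, 1]
    so that 1 marks the most likely heading (argmax = argmin residual)."""
    values = surface.values
    if not np.all(np.isfinite(values)):
        raise ValueError("residual surface contains non-finite values")
    eps = max(values.max() * 1e-12, 1e-300)
    m = np.log(values + eps)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.ones_like(values).reshape(surface.grid.shape)
    return ((hi - m) / (hi - lo)).reshape(surface.grid.shape)
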