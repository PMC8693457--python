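"""Image-plane distortion fields.

A spectacle lens displaces the apparent position of every point in the
visual field.  We describe this with a map ``F`` from undistorted image-plane
coordinates ``(x, y)`` to distorted coordinates ``(x_d, y_d)``.  Coordinates
are tangent-plane units on an image plane at focal distance ``f = 1`` behind
the nodal point (so a point at eccentricity ``e`` from the optic axis sits at
radius ``tan(e)``).  The map is sampled on a rectangular grid (21x21 by
default), bilinearly interpolated between nodes, and differentiated to give
the 2x2 Jacobian that transports flow vectors (distorted flow = J_F @ flow).

No extrapolation is performed anywhere: queries outside the sampled grid are
hard errors, because the distortion is undefined beyond the lens aperture.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DistortionField",
    "GridFormatError",
    "DomainError",
    "InversionError",
    "load_distortion_grid",
    "write_distortion_grid",
]

#: Default grid half-extent in tangent units: covers a 55 deg-radius field of view.
DEFAULT_EXTENT = float(np.tan(np.radians(55.0)))
#: Default number of nodes per axis.
DEFAULT_NODES = 21


class GridFormatError(ValueError):
    """Raised when a distortion grid file is malformed."""


class DomainError(ValueError):
    """Raised when a query point lies outside the sampled grid domain."""


class InversionError(RuntimeError):
    """Raised when the polynomial inverse fails its roundtrip tolerance."""


def _as_points(p) -> tuple[np.ndarray, bool]:
    """Coerce input to an (N, 2) float array; report whether it was a single point."""
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if pts.shape[-1] != 2:
        raise ValueError(f"expected 2-component image points, got shape {arr.shape}")
    return pts, single


def _poly_terms(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (i, j) with i + j <= degree, in a fixed deterministic order."""
    return [(i, j) for total in range(degree + 1) for i in range(total + 1)
            for j in [total - i]]


def _poly_design(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    terms = _poly_terms(degree)
    return np.stack([u ** i * v ** j for i, j in terms], axis=-1)


@dataclass
class DistortionField:
    """Sampled image-plane distortion map ``F`` with interpolation and Jacobian.

    Parameters
    ----------
    sample_xs, sample_ys:
        Strictly increasing 1-D arrays of undistorted node coordinates
        (tangent units).
    mapped_x, mapped_y:
        Arrays of shape ``(len(sample_ys), len(sample_xs))`` holding the
        distorted position of each node, indexed ``[iy, ix]``.
    jacobian_grids:
        Optional ``(dFx_dx, dFx_dy, dFy_dx, dFy_dy)`` node arrays.  When not
        supplied the derivatives are computed by central differences on the
        mapped grid; either way the derivative grids are themselves
        bilinearly interpolated, matching the sampled-derivative scheme.
    gaze_through_lens:
        (horizontal deg, vertical deg) where the line of sight crosses the
        lens; metadata only.
    """

    sample_xs: np.ndarray
    sample_ys: np.ndarray
    mapped_x: np.ndarray
    mapped_y: np.ndarray
    jacobian_grids: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None
    gaze_through_lens: tuple[float, float] = (0.0, 0.0)
    label: str = "unnamed"
    addition_dpt: float = 0.0
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.sample_xs = np.asarray(self.sample_xs, dtype=float)
        self.sample_ys = np.asarray(self.sample_ys, dtype=float)
        self.mapped_x = np.asarray(self.mapped_x, dtype=float)
        self.mapped_y = np.asarray(self.mapped_y, dtype=float)
        ny, nx = len(self.sample_ys), len(self.sample_xs)
        if np.any(np.diff(self.sample_xs) <= 0) or np.any(np.diff(self.sample_ys) <= 0):
            raise GridFormatError("grid axes must be strictly increasing")
        if self.mapped_x.shape != (ny, nx) or self.mapped_y.shape != (ny, nx):
            raise GridFormatError(
                f"mapped grids must have shape {(ny, nx)}, got {self.mapped_x.shape}")
        if not (np.all(np.isfinite(self.mapped_x)) and np.all(np.isfinite(self.mapped_y))):
            raise GridFormatError("mapped positions must be finite")
        if self.jacobian_grids is not None:
            self.jacobian_grids = tuple(
                np.asarray(g, dtype=float) for g in self.jacobian_grids)
            for g in self.jacobian_grids:
                if g.shape != (ny, nx):
                    raise GridFormatError("derivative grids must match the node lattice")
        # Identity maps short-circuit interpolation so that an identity field
        # is bit-transparent (F(p) = p exactly, Jacobian exactly I).
        self._is_identity = (
            np.array_equal(self.mapped_x, np.tile(self.sample_xs, (ny, 1)))
            and np.array_equal(self.mapped_y,
                               np.tile(self.sample_ys[:, None], (1, nx)))
            and self.jacobian_grids is None)
        self._build_interpolators()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_function(cls, func, extent: float = DEFAULT_EXTENT,
                      nodes: int = DEFAULT_NODES, **meta) -> "DistortionField":
        """Sample an analytic map ``func((N,2) array) -> (N,2) array`` on the lattice."""
        xs = np.linspace(-extent, extent, nodes)
        ys = np.linspace(-extent, extent, nodes)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        mapped = np.asarray(func(pts), dtype=float)
        return cls(xs, ys, mapped[:, 0].reshape(gx.shape),
                   mapped[:, 1].reshape(gx.shape), **meta)

    def _build_interpolators(self):
        if self.jacobian_grids is None:
            # Central differences (one-sided at the borders) on the mapped grid.
            dx = np.gradient(self.sample_xs)
            dy = np.gradient(self.sample_ys)
            dfx_dx = np.gradient(self.mapped_x, axis=1) / dx[None, :]
            dfx_dy = np.gradient(self.mapped_x, axis=0) / dy[:, None]
            dfy_dx = np.gradient(self.mapped_y, axis=1) / dx[None, :]
            dfy_dy = np.gradient(self.mapped_y, axis=0) / dy[:, None]
            jac = (dfx_dx, dfx_dy, dfy_dx, dfy_dy)
        else:
            jac = self.jacobian_grids
        grids = dict(fx=self.mapped_x, fy=self.mapped_y,
                     j00=jac[0], j01=jac[1], j10=jac[2], j11=jac[3])
        self._interp = {
            name: RegularGridInterpolator(
                (self.sample_ys, self.sample_xs), values,
                method="linear", bounds_error=True)
            for name, values in grids.items()
        }

    # -- queries ---------------------------------------------------------------

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.sample_xs[0], self.sample_xs[-1],
                self.sample_ys[0], self.sample_ys[-1])

    def contains(self, p) -> np.ndarray:
        pts, single = _as_points(p)
        x0, x1, y0, y1 = self.extent
        ok = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1) &
              (pts[:, 1] >= y0) & (pts[:, 1] <= y1))
        return ok[0] if single else ok

    def _query(self, name: str, pts: np.ndarray) -> np.ndarray:
        try:
            return self._interp[name](pts[:, ::-1])  # interpolator is (y, x)-ordered
        except ValueError as exc:
            raise DomainError(
                f"query outside distortion grid domain {self.extent}: {exc}") from None

    def _check_domain(self, pts: np.ndarray) -> None:
        if not np.all(self.contains(pts)):
            raise DomainError(f"query outside distortion grid domain {self.extent}")

    def __call__(self, p):
        """Evaluate ``F`` at image point(s) ``p`` by bilinear interpolation."""
        pts, single = _as_points(p)
        if self._is_identity:
            self._check_domain(pts)
            return pts[0].copy() if single else pts.copy()
        out = np.column_stack([self._query("fx", pts), self._query("fy", pts)])
        return out[0] if single else out

    def jacobian(self, p):
        """2x2 Jacobian(s) ``dF/d(x,y)`` at ``p``, from the derivative grids."""
        pts, single = _as_points(p)
        if self._is_identity:
            self._check_domain(pts)
            j = np.broadcast_to(np.eye(2), (len(pts), 2, 2)).copy()
            return j[0] if single else j
        j = np.empty((len(pts), 2, 2))
        j[:, 0, 0] = self._query("j00", pts)
        j[:, 0, 1] = self._query("j01", pts)
        j[:, 1, 0] = self._query("j10", pts)
        j[:, 1, 1] = self._query("j11", pts)
        return j[0] if single else j

    # -- inverse ---------------------------------------------------------------

    def fit_inverse(self, degree: int = 9) -> None:
        """Precompute the polynomial approximation of ``F^-1``.

        Least-squares fit, per component, of a total-degree-``degree``
        bivariate polynomial mapping distorted node positions back to the
        undistorted nodes.  Coordinates are rescaled to ~[-1, 1] before
        fitting for conditioning.
        """
        gx, gy = np.meshgrid(self.sample_xs, self.sample_ys)
        xd = self.mapped_x.ravel()
        yd = self.mapped_y.ravel()
        scale = max(np.abs(xd).max(), np.abs(yd).max(), 1e-12)
        design = _poly_design(xd / scale, yd / scale, degree)
        coef, *_ = np.linalg.lstsq(design, np.column_stack([gx.ravel(), gy.ravel()]),
                                   rcond=None)
        self._inverse = (degree, scale, coef)

    def inverse(self, pd, tol: float = 1e-3):
        """Approximate ``F^-1(pd)`` via the fitted polynomial.

        Raises :class:`InversionError` when the roundtrip error ``|F(q) - pd|``
        exceeds ``tol`` (checked wherever ``q`` falls inside the grid domain),
        which flags folded or poorly-fit fields.
        """
        if not hasattr(self, "_inverse"):
            self.fit_inverse()
        degree, scale, coef = self._inverse
        pts, single = _as_points(pd)
        q = _poly_design(pts[:, 0] / scale, pts[:, 1] / scale, degree) @ coef
        inside = self.contains(q)
        if np.any(inside):
            err = np.linalg.norm(self(q[inside]) - pts[inside], axis=-1)
            if err.max() > tol:
                raise InversionError(
                    f"inverse roundtrip error {err.max():.3g} exceeds tol {tol:g}; "
                    "field may be folded or the fit degree too low")
        return q[0] if single else q


# -- grid file I/O -------------------------------------------------------------

_BASE_COLS = ["x", "y", "x_d", "y_d"]
_DERIV_COLS = ["dFx_dx", "dFx_dy", "dFy_dx", "dFy_dy"]


def load_distortion_grid(path) -> DistortionField:
    """Read a distortion grid from the plain-text tabular dialect.

    Format: leading ``#`` comment lines carrying ``key: value`` metadata
    (``lens``, ``addition_dpt``, ``gaze_through_lens_deg``), a header line,
    then one comma-separated row per node, row-major over the lattice, with
    columns ``x, y, x_d, y_d`` and optionally the four Jacobian components.
    """
    meta = {}
    rows = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, value = body.split(":", 1)
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:4] != _BASE_COLS or header[4:] not in ([], _DERIV_COLS):
                    raise GridFormatError(
                        f"{path}: line {lineno}: unexpected header {header}")
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise GridFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise GridFormatError(
                    f"{path}: line {lineno}: non-numeric value in row {line!r}"
                ) from None
    if header is None or not rows:
        raise GridFormatError(f"{path}: no data rows found")
    data = np.asarray(rows)
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    nx, ny = len(xs), len(ys)
    if nx < 2 or ny < 2:
        raise GridFormatError(
            f"{path}: lattice needs at least 2x2 nodes, got {ny}x{nx}")
    if nx * ny != len(data):
        raise GridFormatError(
            f"{path}: {len(data)} rows do not form a complete {ny}x{nx} lattice")
    # Row-major: y varies slowest. Verify lattice ordering node by node.
    exp_x = np.tile(xs, ny)
    exp_y = np.repeat(ys, nx)
    mismatch = np.nonzero((data[:, 0] != exp_x) | (data[:, 1] != exp_y))[0]
    if mismatch.size:
        raise GridFormatError(
            f"{path}: data row {mismatch[0] + 1} out of row-major lattice order")
    jac = None
    if data.shape[1] == 8:
        jac = tuple(data[:, 4 + k].reshape(ny, nx) for k in range(4))
    gaze = (0.0, 0.0)
    if "gaze_through_lens_deg" in meta:
        gh, gv = meta["gaze_through_lens_deg"].split()
        gaze = (float(gh), float(gv))
    return DistortionField(
        xs, ys, data[:, 2].reshape(ny, nx), data[:, 3].reshape(ny, nx),
        jacobian_grids=jac, gaze_through_lens=gaze,
        label=meta.get("lens", "unnamed"),
        addition_dpt=float(meta.get("addition_dpt", 0.0)))


def write_distortion_grid(field: DistortionField, path,
                          include_jacobian: bool = False) -> None:
    """Write ``field`` in the same dialect :func:`load_distortion_grid` reads."""
    cols = _BASE_COLS + (_DERIV_COLS if include_jacobian else [])
    buf = io.StringIO()
    buf.write(f"# lens: {field.label}\n")
    buf.write(f"# addition_dpt: {field.addition_dpt!r}\n")
    gh, gv = field.gaze_through_lens
    buf.write(f"# gaze_through_lens_deg: {gh!r} {gv!r}\n")
    buf.write(",".join(cols) + "\n")
    jac = field.jacobian_grids
    if include_jacobian and jac is None:
        raise ValueError("field carries no explicit derivative grids")
    for iy, y in enumerate(field.sample_ys):
        for ix, x in enumerate(field.sample_xs):
            vals = [x, y, field.mapped_x[iy, ix], field.mapped_y[iy, ix]]
            if include_jacobian:
                vals += [g[iy, ix] for g in jac]
            buf.write(",".join(repr(float(v)) for v in vals) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
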