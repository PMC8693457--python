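"""Synthetic stand-ins for the study's external inputs.

Three generators live here:

* a parametric progressive-addition-lens (PAL) model producing distortion
  fields per gaze direction.  Real PAL ray-trace data are proprietary, so we
  use a closed-form surrogate: a spherical-power corridor running down the
  lens from the far zone (0 dpt) to the near zone (far + addition, 2 dpt by
  default), flanked by unwanted astigmatism that grows laterally off the
  corridor at the Minkwitz rate (lateral astigmatism gradient = twice the
  power gradient along the corridor).  A ray crossing the lens at angular
  position l (degrees from the eye's nodal point) is deviated by the
  prismatic effect of the local power matrix P(l) acting at the decentration
  h = q*l_rad (Prentice's rule, small-angle), with q the eye-lens distance.
  Every downstream number therefore has an analytic oracle.

* analytic distortion fields (identity / magnification / skew / rotation)
  used as fixtures with exactly known Jacobians.

* a Bernoulli observer drawing up/down responses from a cumulative-normal
  psychometric curve, standing in for human participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distortion import DEFAULT_EXTENT, DEFAULT_NODES, DistortionField
from .geometry import field_deg_to_tangent, tangent_to_field_deg

__all__ = [
    "SyntheticLens",
    "ObserverModel",
    "synthesize_pal",
    "distortion_for_gaze",
    "analytic_distortion",
    "simulate_observer",
]


@dataclass(frozen=True)
class SyntheticLens:
    """Parametric PAL description.

    far_power / addition are dioptres; the far zone is plano and the near
    zone has +2 dpt by default.  corridor_length is the angular extent
    (degrees, as seen from the eye) over which the power progresses;
    corridor_center its midpoint in lens coordinates (x right, y up, both
    degrees).  lateral_falloff (deg) saturates the off-corridor astigmatism
    growth.  eye_lens_distance is in metres (12 mm vertex distance plus
    7.3 mm nodal-point depth); aperture_radius bounds valid lens angles.
    """

    far_power: float = 0.0
    addition: float = 2.0
    corridor_length: float = 60.0
    corridor_center: tuple[float, float] = (0.0, -15.0)
    lateral_falloff: float = 20.0
    eye_lens_distance: float = 0.0193
    aperture_radius: float = 85.0

    def __post_init__(self):
        if self.addition < 0:
            raise ValueError("addition power must be >= 0")
        if self.corridor_length <= 0:
            raise ValueError("corridor_length must be positive")
        if self.lateral_falloff <= 0:
            raise ValueError("lateral_falloff must be positive")


class PalDeflectionModel:
    """Closed-form deflection model for a :class:`SyntheticLens`.

    ``power_matrix(l)`` returns the local 2x2 dioptric power matrix at lens
    angle ``l`` (deg): mean sphere S(l_y) on the diagonal plus an oblique
    (cross-cylinder) term X(l) = S'(l_y) * falloff * tanh(l_x / falloff),
    odd in l_x so the lens is mirror-symmetric about the corridor.
    ``deflection(l)`` is the small-angle prismatic deviation (radians)
    P(l) @ (q * l_rad).
    """

    def __init__(self, lens: SyntheticLens):
        self.lens = lens
        # Logistic scale: the 10-90% power progression spans ~0.73*corridor_length.
        self._w = lens.corridor_length / 4.0

    def sphere(self, ly):
        """Mean spherical power S (dpt) as a function of vertical lens angle."""
        lens = self.lens
        z = (lens.corridor_center[1] - np.asarray(ly, dtype=float)) / self._w
        return lens.far_power + lens.addition / (1.0 + np.exp(-z))

    def sphere_gradient(self, ly):
        """dS/dl_y in dpt/deg (negative: power grows downward)."""
        lens = self.lens
        z = (lens.corridor_center[1] - np.asarray(ly, dtype=float)) / self._w
        sig = 1.0 / (1.0 + np.exp(-z))
        return -lens.addition * sig * (1.0 - sig) / self._w

    def cross_power(self, lx, ly):
        """Oblique astigmatic power X (dpt); odd in the lateral coordinate."""
        lens = self.lens
        cx = lens.corridor_center[0]
        lat = np.asarray(lx, dtype=float) - cx
        return (np.abs(self.sphere_gradient(ly)) * lens.lateral_falloff
                * np.tanh(lat / lens.lateral_falloff))

    def power_matrix(self, l):
        """Local power matrix at lens angle(s) ``l``: (..., 2, 2), dioptres."""
        l = np.asarray(l, dtype=float)
        s = self.sphere(l[..., 1])
        x = self.cross_power(l[..., 0], l[..., 1])
        out = np.empty(l.shape[:-1] + (2, 2))
        out[..., 0, 0] = s
        out[..., 1, 1] = s
        out[..., 0, 1] = x
        out[..., 1, 0] = x
        return out

    def deflection(self, l):
        """Prismatic ray deviation (radians, 2-vector) at lens angle(s) ``l`` (deg)."""
        l = np.asarray(l, dtype=float)
        h = self.lens.eye_lens_distance * np.radians(l)  # decentration, metres
        p = self.power_matrix(l)
        return np.einsum("...ij,...j->...i", p, h)


def synthesize_pal(lens: SyntheticLens) -> PalDeflectionModel:
    """Build the closed-form deflection model for ``lens``."""
    return PalDeflectionModel(lens)


def distortion_for_gaze(model: PalDeflectionModel,
                        gaze_through_lens: tuple[float, float],
                        extent: float = DEFAULT_EXTENT,
                        nodes: int = DEFAULT_NODES) -> DistortionField:
    """Sample the lens model into a :class:`DistortionField` for one gaze direction.

    A visual-field point at angular position ``theta`` (deg relative to gaze)
    crosses the lens at ``l = gaze + theta`` (small-angle composition).  The
    map is gaze-anchored: the deflection at the gaze point itself is
    subtracted so F(0) = 0, since the eye fixates *through* the lens.
    """
    gaze = np.asarray(gaze_through_lens, dtype=float)
    if np.linalg.norm(gaze) > model.lens.aperture_radius:
        raise ValueError(
            f"gaze point {tuple(gaze)} outside lens aperture "
            f"(radius {model.lens.aperture_radius} deg)")

    def mapper(pts: np.ndarray) -> np.ndarray:
        theta = tangent_to_field_deg(pts)
        delta = (np.degrees(model.deflection(gaze + theta))
                 - np.degrees(model.deflection(gaze)))
        # Differential form: bit-exact identity when the deflection vanishes.
        return pts + (field_deg_to_tangent(theta + delta)
                      - field_deg_to_tangent(theta))

    side = "central" if np.allclose(gaze, 0) else "peripheral"
    return DistortionField.from_function(
        mapper, extent=extent, nodes=nodes,
        gaze_through_lens=(float(gaze[0]), float(gaze[1])),
        label=f"synthetic-pal-{side}",
        addition_dpt=model.lens.addition)


def analytic_distortion(kind: str, param: float = 0.0,
                        extent: float = DEFAULT_EXTENT,
                        nodes: int = DEFAULT_NODES) -> DistortionField:
    """Closed-form test fields: identity | magnification | skew | rotation.

    ``param`` is the scale factor for magnification, the shear coefficient k
    in (x + k*y, y) for skew, and the anti-clockwise angle in degrees for
    rotation.
    """
    if kind == "identity":
        mat = np.eye(2)
    elif kind == "magnification":
        mat = param * np.eye(2)
    elif kind == "skew":
        mat = np.array([[1.0, param], [0.0, 1.0]])
    elif kind == "rotation":
        t = np.radians(param)
        mat = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    else:
        raise ValueError(f"unknown analytic distortion kind {kind!r}")
    return DistortionField.from_function(
        lambda pts: pts @ mat.T, extent=extent, nodes=nodes,
        label=f"analytic-{kind}")


# -- synthetic observer --------------------------------------------------------


@dataclass(frozen=True)
class ObserverModel:
    """Stationary psychometric observer: p(up | angle) follows a cumulative
    normal with point of subjective equality ``true_pse`` (deg), slope
    parameter ``spread`` (deg) and lapse rate ``lapse`` (shared asymptote)."""

    true_pse: float = 0.0
    spread: float = 1.0
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def p_up(self, angles):
        from scipy.stats import norm
        z = (np.asarray(angles, dtype=float) - self.true_pse) / self.spread
        return self.lapse + (1 - 2 * self.lapse) * norm.cdf(z)


def simulate_observer(obs: ObserverModel, angles, reps: int) -> pd.DataFrame:
    """Draw ``reps`` Bernoulli up/down responses per angle; reproducible by seed.

    Returns a tidy frame with columns angle, n_trials, n_up.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(obs.seed)
    angles = np.asarray(angles, dtype=float)
    p = obs.p_up(angles)
    n_up = rng.binomial(reps, p)
    return pd.DataFrame({"angle": angles,
                         "n_trials": float(reps),
                         "n_up": n_up.astype(float)})
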