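import numpy as np
import pytest

import palflow as pf


@pytest.fixture(scope="session")
def scenario() -> pf.MotionScenario:
    """Protocol-default walking scenario (2 m/s, gaze 20 deg down, 1.8 m)."""
    return pf.MotionScenario()


@pytest.fixture(scope="session")
def pal_model():
    return pf.synthesize_pal(pf.SyntheticLens())


@pytest.fixture(scope="session")
def central_field(pal_model):
    return pf.distortion_for_gaze(pal_model, (0.0, 0.0))


@pytest.fixture(scope="session")
def peripheral_field(pal_model):
    return pf.distortion_for_gaze(pal_model, (20.0, -20.0))


@pytest.fixture(scope="session")
def coarse_grid() -> pf.HeadingGrid:
    """1-degree candidate grid for fast tests."""
    return pf.HeadingGrid(step=1.0)


@pytest.fixture(scope="session")
def default_patches(scenario):
    return pf.sample_patches(55.0, 50, scenario, seed=1234)


def dense_subspace_residual(positions, velocities, direction):
    """Independent oracle: explicit least squares over inverse depths and the
    torsion-free rotation, using the full stacked constraint matrix."""
    positions = np.atleast_2d(positions)
    velocities = np.atleast_2d(velocities)
    t = np.asarray(direction, float)
    t = t / np.linalg.norm(t)
    n = len(positions)
    v = velocities.reshape(-1)
    c = np.zeros((2 * n, n + 2))
    for i, (x, y) in enumerate(positions):
        a = np.array([[-1.0, 0.0, x], [0.0, -1.0, y]])
        c[2 * i:2 * i + 2, i] = a @ t
        b = np.array([[x * y, -(1 + x * x)], [1 + y * y, -x * y]])
        c[2 * i:2 * i + 2, n:] = b
    sol, *_ = np.linalg.lstsq(c, v, rcond=None)
    r = v - c @ sol
    return float(r @ r)
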