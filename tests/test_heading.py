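import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import palflow as pf
from conftest import dense_subspace_residual


class TestPatchArea:
    @pytest.mark.parametrize("ecc,expected", [(0.0, 1.0816), (10.0, 50.9796)])
    def test_receptive_field_scaling(self, ecc, expected):
        assert pf.patch_area(ecc) == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.0, 54.0), st.floats(0.01, 1.0))
    def test_strictly_increasing(self, ecc, step):
        assert pf.patch_area(ecc + step) > pf.patch_area(ecc)

    def test_negative_eccentricity_rejected(self):
        with pytest.raises(ValueError):
            pf.patch_area(-1.0)


class TestSamplePatches:
    def test_default_protocol_counts(self, default_patches):
        assert len(default_patches) == 50
        assert all(len(p.points) == 10 for p in default_patches)

    def test_geometry_constraints(self, default_patches):
        for p in default_patches:
            assert p.radius == pytest.approx(np.sqrt(p.area / np.pi))
            assert p.area == pytest.approx(pf.patch_area(p.eccentricity))
            # points inside the patch disc and the FoV
            d = np.linalg.norm(p.points_deg - np.asarray(p.center_deg), axis=1)
            assert np.all(d <= p.radius + 1e-9)
            assert p.max_point_eccentricity <= 55.0 + 1e-9

    def test_points_all_on_visible_ground(self, scenario, default_patches):
        for p in default_patches:
            ground = pf.ray_to_ground(p.points, scenario)
            assert np.all(np.isfinite(ground))
            assert np.all(ground[:, 2] > 0)

    def test_seed_determinism(self, scenario):
        a = pf.sample_patches(55.0, 8, scenario, seed=3)
        b = pf.sample_patches(55.0, 8, scenario, seed=3)
        c = pf.sample_patches(55.0, 8, scenario, seed=4)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.points, pb.points)
        assert not np.allclose([p.center_deg for p in a],
                               [p.center_deg for p in c])


class TestHeadingGrid:
    def test_protocol_node_conventions(self):
        grid = pf.HeadingGrid(step=0.25)
        assert grid.shape == (281, 81)
        # Ground-parallel translation toward the fixation point is a node...
        idx = grid.node_index(0.0, 20.0)
        d = grid.directions[idx]
        sc = pf.MotionScenario(heading_azimuth_world=0.0,
                               heading_vertical_world=0.0)
        np.testing.assert_allclose(d, sc.translation_retinal / sc.speed,
                                   atol=1e-12)
        # ... and so is every protocol heading (offset +-20, angles in 0.5 steps).
        for az in (-20.0, 20.0):
            for v in np.arange(-3.5, 3.51, 0.5):
                grid.node_index(az, 20.0 + v)

    def test_step_must_divide_span(self):
        with pytest.raises(ValueError):
            pf.HeadingGrid(step=0.3)


class TestSubspaceResidual:
    @staticmethod
    def synthesize_flow(rng, n, direction):
        """Flow exactly explained by `direction`, random inverse depths and a
        random torsion-free rotation."""
        pos = rng.uniform(-1.0, 1.0, size=(n, 2))
        inv_depth = rng.uniform(0.1, 2.0, size=n)
        omega = np.array([rng.normal(0, 0.1), rng.normal(0, 0.1), 0.0])
        vel = np.empty((n, 2))
        for i, (x, y) in enumerate(pos):
            a = np.array([[-1.0, 0, x], [0, -1.0, y]])
            b = np.array([[x * y, -(1 + x * x), y], [1 + y * y, -x * y, -x]])
            vel[i] = inv_depth[i] * (a @ direction) + b @ omega
        return pos, vel

    def test_zero_at_generating_direction(self):
        rng = np.random.default_rng(11)
        direction = np.array([0.2, 0.3, 0.9])
        direction /= np.linalg.norm(direction)
        pos, vel = self.synthesize_flow(rng, 10, direction)
        assert pf.subspace_residual(pos, vel, direction) < 1e-24
        off = direction + [0.05, 0.0, 0.0]
        assert pf.subspace_residual(pos, vel, off / np.linalg.norm(off)) > 1e-8

    def test_single_vector_is_uninformative(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-1, 1, (1, 2))
        vel = rng.normal(size=(1, 2))
        for _ in range(5):
            d = rng.normal(size=3)
            assert pf.subspace_residual(pos, vel, d) < 1e-20

    def test_matches_dense_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(2, 11)
            pos = rng.uniform(-1.2, 1.2, size=(n, 2))
            vel = rng.normal(scale=0.3, size=(n, 2))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            mine = pf.subspace_residual(pos, vel, d)
            oracle = dense_subspace_residual(pos, vel, d)
            assert mine == pytest.approx(oracle, rel=1e-8, abs=1e-14)

    def test_scale_invariance_of_argmin(self, scenario, coarse_grid,
                                        default_patches):
        field = pf.build_flow_field(scenario, default_patches[:5])
        pos, vel = field.positions[0], field.velocities[0]
        s1 = pf.residual_surface(pos, vel, coarse_grid)
        s2 = pf.residual_surface(pos, 3.0 * vel, coarse_grid)
        np.testing.assert_allclose(s2.values, 9.0 * s1.values, rtol=1e-9)


class TestResidualSurface:
    def test_minimum_at_truth_for_noiseless_patch(self, scenario, coarse_grid):
        patches = pf.sample_patches(55.0, 3, scenario, seed=21)
        field = pf.build_flow_field(scenario, patches)
        idx = coarse_grid.node_index(scenario.heading_azimuth_world,
                                     20.0 + scenario.heading_vertical_world)
        for pos, vel in zip(field.positions, field.velocities):
            surf = pf.residual_surface(pos, vel, coarse_grid)
            assert np.all(surf.values >= 0)
            assert surf.values[idx] <= surf.values.min() + 1e-18

    def test_mirrored_patch_gives_mirrored_surface(self, scenario, coarse_grid):
        left = pf.MotionScenario(heading_azimuth_world=-20.0)
        patches = pf.sample_patches(55.0, 2, scenario, seed=31)
        f = pf.build_flow_field(scenario, patches)
        pos, vel = f.positions[0], f.velocities[0]
        surf = pf.residual_surface(pos, vel, coarse_grid).as_array()
        om_l = pf.solve_fixation_rotation(left)
        g_l = pf.ray_to_ground(pos * [-1.0, 1.0], left)
        vel_l = pf.flow_vector(g_l, left.translation_retinal, om_l)
        surf_l = pf.residual_surface(pos * [-1.0, 1.0], vel_l,
                                     coarse_grid).as_array()
        np.testing.assert_allclose(surf_l, surf[::-1, :], atol=1e-12)


class TestEstimateHeading:
    def test_exact_recovery_of_protocol_heading(self, scenario, coarse_grid,
                                                default_patches):
        field = pf.build_flow_field(scenario, default_patches)
        est, total = pf.estimate_heading(field, coarse_grid)
        assert (est.azimuth, est.elevation) == (20.0, 20.0)
        assert est.world_vertical == 0.0
        assert est.residual < 1e-12 * total.values.max()

    def test_identity_distortion_same_estimate(self, scenario, coarse_grid,
                                               default_patches):
        ident = pf.analytic_distortion("identity")
        e1, s1 = pf.estimate_heading(
            pf.build_flow_field(scenario, default_patches), coarse_grid)
        e2, s2 = pf.estimate_heading(
            pf.build_flow_field(scenario, default_patches, ident), coarse_grid)
        assert (e1.azimuth, e1.elevation) == (e2.azimuth, e2.elevation)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_distorted_argmin_matches_bruteforce_oracle(self, scenario,
                                                        peripheral_field):
        grid = pf.HeadingGrid(step=2.0)
        patches = pf.sample_patches(55.0, 10, scenario, seed=9)
        field = pf.build_flow_field(scenario, patches, peripheral_field)
        est, total = pf.estimate_heading(field, grid)
        brute = np.zeros(len(grid))
        for pos, vel in zip(field.positions, field.velocities):
            for g, d in enumerate(grid.directions):
                brute[g] += dense_subspace_residual(pos, vel, d)
        assert np.argmin(brute) == est.index
        np.testing.assert_allclose(total.values, brute, rtol=1e-8, atol=1e-15)

    def test_fov_filter_retains_nested_subsets(self, scenario, default_patches):
        retained = {
            r: {i for i, p in enumerate(default_patches)
                if p.max_point_eccentricity <= r}
            for r in (40.0, 45.0, 50.0, 55.0)}
        assert retained[40.0] <= retained[45.0] <= retained[50.0] <= retained[55.0]
        assert retained[55.0] == set(range(50))

    def test_no_informative_patch_raises(self, scenario, coarse_grid):
        patches = pf.sample_patches(55.0, 2, scenario, seed=1, n_points=1)
        field = pf.build_flow_field(scenario, patches)
        with pytest.raises(pf.EstimationError):
            pf.estimate_heading(field, coarse_grid)


class TestLikelihoodMap:
    def test_argmax_is_argmin_of_residual(self, scenario, coarse_grid,
                                          peripheral_field, default_patches):
        field = pf.build_flow_field(scenario, default_patches, peripheral_field)
        est, total = pf.estimate_heading(field, coarse_grid)
        like = pf.to_likelihood_map(total)
        assert like.shape == coarse_grid.shape
        assert like.max() == 1.0 and like.min() == 0.0
        assert np.unravel_index(np.argmax(like), like.shape) == \
            np.unravel_index(est.index, coarse_grid.shape)

    def test_surface_tabular_view(self, coarse_grid):
        surf = pf.ResidualSurface(coarse_grid,
                                  np.arange(float(len(coarse_grid))), 10)
        frame = surf.to_frame()
        assert len(frame) == len(coarse_grid)
        idx = coarse_grid.node_index(0.0, 20.0)
        row = frame.iloc[idx]
        assert (row["azimuth"], row["elevation"]) == (0.0, 20.0)
        assert row["residual"] == float(idx)

    def test_constant_surface_gives_uniform_map(self, coarse_grid):
        surf = pf.ResidualSurface(coarse_grid, np.ones(len(coarse_grid)), 10)
        np.testing.assert_array_equal(pf.to_likelihood_map(surf), 1.0)

    def test_distorted_map_elongated_vertically(self, scenario, coarse_grid,
                                                peripheral_field,
                                                default_patches):
        """Distortion spreads the likely headings mainly along the vertical
        axis of heading space."""
        field = pf.build_flow_field(scenario, default_patches, peripheral_field)
        _, total = pf.estimate_heading(field, coarse_grid)
        like = pf.to_likelihood_map(total)
        good = np.argwhere(like >= 0.95)
        az_spread = np.ptp(coarse_grid.azimuths[good[:, 0]])
        el_spread = np.ptp(coarse_grid.elevations[good[:, 1]])
        assert el_spread >= az_spread
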