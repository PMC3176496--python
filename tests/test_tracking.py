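"""Seed generation, fiber tracing, batch contract, streamline baseline."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from geotract.geodesic import christoffel, geodesic_rhs
from geotract.phantoms import make_curved, make_halfplane, make_homogeneous
from geotract.providers import ConstantFieldProvider, GridFieldProvider
from geotract.tensors import precompute
from geotract.tracking import (
    DegenerateDirectionError,
    SeedSpec,
    TrackingConfig,
    generate_directions,
    generate_seeds,
    trace_batch,
    trace_fiber,
    trace_streamline,
)


class TestGenerateDirections:
    @pytest.mark.parametrize("mode", ["uniform_sphere", "around_main_eigenvector"])
    def test_unit_norm(self, mode):
        rng = np.random.default_rng(0)
        dirs = generate_directions(5, mode, axis=np.array([0.0, 0, 1]), cone_angle=0.5, rng=rng)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)

    def test_zero_cone_collapses_to_axis(self):
        axis = np.array([1.0, 2.0, 2.0]) / 3.0
        dirs = generate_directions(
            7, "around_main_eigenvector", axis, 0.0, np.random.default_rng(1)
        )
        np.testing.assert_allclose(dirs, np.tile(axis, (7, 1)), atol=1e-12)

    def test_cone_angle_respected(self):
        axis = np.array([0.0, 0.0, 1.0])
        dirs = generate_directions(
            500, "around_main_eigenvector", axis, 0.3, np.random.default_rng(2)
        )
        assert np.all(dirs @ axis >= np.cos(0.3) - 1e-12)

    def test_uniform_sphere_mean_is_small(self):
        dirs = generate_directions(10000, "uniform_sphere", rng=np.random.default_rng(3))
        assert np.linalg.norm(dirs.mean(axis=0)) < 3 / np.sqrt(10000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_directions(0, "uniform_sphere")
        with pytest.raises(ValueError):
            generate_directions(3, "around_main_eigenvector", np.zeros(3), 0.1)


class TestGenerateSeeds:
    def test_explicit_points_cartesian_product(self, homogeneous_fields):
        spec = SeedSpec(
            points=[[5, 5, 5], [6, 6, 6], [7, 7, 7]],
            direction_mode="uniform_sphere",
            directions_per_seed=4,
        )
        pairs = generate_seeds(spec, homogeneous_fields, rng_seed=0)
        assert len(pairs) == 12

    def test_box_region_positions_in_bounds(self, homogeneous_fields):
        spec = SeedSpec(region=((2, 2, 2), (60, 13, 13)), n_seeds=100)
        pairs = generate_seeds(spec, homogeneous_fields, rng_seed=1)
        pos = np.array([p for p, _ in pairs])
        assert np.all(pos >= 2) and np.all(pos <= [60, 13, 13])

    def test_cone_mode_follows_main_eigenvector(self, homogeneous_fields):
        spec = SeedSpec(
            points=[[10, 8, 8], [30, 8, 8]],
            direction_mode="around_main_eigenvector",
            cone_angle=0.0,
            directions_per_seed=3,
        )
        pairs = generate_seeds(spec, homogeneous_fields, rng_seed=2)
        for _, d in pairs:
            np.testing.assert_allclose(np.abs(d), [1.0, 0.0, 0.0], atol=1e-10)

    def test_region_outside_volume_rejected(self, homogeneous_fields):
        with pytest.raises(ValueError):
            generate_seeds(
                SeedSpec(region=((100, 100, 100), (200, 200, 200)), n_seeds=3),
                homogeneous_fields,
                rng_seed=0,
            )

    def test_deterministic_given_seed(self, homogeneous_fields):
        spec = SeedSpec(region=((2, 2, 2), (60, 13, 13)), n_seeds=20, directions_per_seed=2)
        a = generate_seeds(spec, homogeneous_fields, rng_seed=11)
        b = generate_seeds(spec, homogeneous_fields, rng_seed=11)
        for (pa, da), (pb, db) in zip(a, b):
            np.testing.assert_array_equal(pa, pb)
            np.testing.assert_array_equal(da, db)


class TestTraceFiber:
    def test_homogeneous_isotropic_straight_line(self):
        fields = precompute(make_homogeneous((16, 8, 8), (1, 1, 1), (1, 0, 0)))
        provider = GridFieldProvider(fields)
        cfg = TrackingConfig(h=0.1, max_steps=50)
        fiber = trace_fiber([5.0, 4.0, 4.0], [1.0, 0.0, 0.0], cfg, provider)
        assert fiber.termination == "max_steps"
        assert fiber.n_points == 51
        expected = np.column_stack(
            [5.0 + 0.1 * np.arange(51), np.full(51, 4.0), np.full(51, 4.0)]
        )
        np.testing.assert_allclose(fiber.points, expected, atol=1e-12)

    def test_immediate_exit(self, halfplane_grid_provider):
        cfg = TrackingConfig(h=0.1, max_steps=100)
        fiber = trace_fiber([0.5, 30.0, 4.0], [-1.0, 0.0, 0.0], cfg, halfplane_grid_provider)
        assert fiber.termination == "left_volume"
        assert 1 <= fiber.n_points <= 8

    def test_halfplane_semicircle_against_adaptive_oracle(self, halfplane_grid_provider):
        """The fixed-step RK2 trace on the interpolated grid field matches
        a tight-tolerance adaptive integration of the same field, and the
        path follows the semicircle geometry of the half-plane metric."""
        cfg = TrackingConfig(h=0.05, max_steps=1000, solver="rk2")
        fiber = trace_fiber([32.0, 15.0, 4.0], [1.0, 0.0, 0.0], cfg, halfplane_grid_provider)
        assert fiber.termination == "max_steps"
        y = fiber.points[:, 1] + 1.0
        residual = np.abs((fiber.points[:, 0] - 32.0) ** 2 + y**2 - 256.0) / 256.0
        assert residual.max() < 0.05  # semicircle up to grid discretization

        def rhs(_, s):
            d, gx, gy, gz = halfplane_grid_provider.evaluate_many(s[None, :3])
            acc = geodesic_rhs(s[3:], christoffel(d[0], gx[0], gy[0], gz[0]))
            return np.concatenate([s[3:], acc])

        sol = solve_ivp(rhs, (0, 50.0), [32, 15, 4, 1, 0, 0], rtol=1e-10, atol=1e-12)
        assert np.linalg.norm(fiber.points[-1] - sol.y[:3, -1]) < 0.05

    def test_halfplane_closed_form_on_analytic_field(self, halfplane_analytic):
        """On the exact field the traced fiber hits the closed-form
        point x = c + r tanh(tau/r), y = r sech(tau/r) and stays on its
        semicircle."""
        cfg = TrackingConfig(h=0.05, max_steps=1000, solver="rk2")
        fiber = trace_fiber([32.0, 15.0, 4.0], [1.0, 0.0, 0.0], cfg, halfplane_analytic)
        ref = halfplane_analytic.geodesic_point(32.0, 16.0, 50.0)
        ref[2] = 4.0
        assert np.linalg.norm(fiber.points[-1] - ref) < 0.5
        y = fiber.points[:, 1] + 1.0
        residual = np.abs((fiber.points[:, 0] - 32.0) ** 2 + y**2 - 256.0) / 256.0
        assert residual.max() < 0.02

    def test_invalid_seeds_raise(self, halfplane_grid_provider):
        cfg = TrackingConfig()
        with pytest.raises(ValueError):
            trace_fiber([-5.0, 5.0, 5.0], [1, 0, 0], cfg, halfplane_grid_provider)
        with pytest.raises(ValueError):
            trace_fiber([5.0, 5.0, 5.0], [0, 0, 0], cfg, halfplane_grid_provider)

    def test_point_count_law(self, halfplane_grid_provider):
        """points = 1 + completed steps, never above max_steps + 1."""
        for max_steps in (1, 17, 400):
            cfg = TrackingConfig(h=0.05, max_steps=max_steps)
            fiber = trace_fiber([32.0, 15.0, 4.0], [1.0, 0, 0], cfg, halfplane_grid_provider)
            assert fiber.n_points <= max_steps + 1
            if fiber.termination == "max_steps":
                assert fiber.n_points == max_steps + 1


class TestTraceBatch:
    def _seeds(self, n=13):
        rng = np.random.default_rng(4)
        seeds = []
        for _ in range(n):
            pos = rng.uniform([10, 10, 2], [50, 50, 6])
            d = rng.normal(size=3)
            seeds.append((pos, d / np.linalg.norm(d)))
        return seeds

    def test_batch_equals_sequential(self, halfplane_grid_provider):
        cfg = TrackingConfig(h=0.1, max_steps=60)
        seeds = self._seeds()
        batch = trace_batch(seeds, cfg, halfplane_grid_provider)
        for fiber, seed in zip(batch, seeds):
            single = trace_fiber(seed[0], seed[1], cfg, halfplane_grid_provider)
            assert fiber.termination == single.termination
            np.testing.assert_allclose(fiber.points, single.points, atol=1e-12)

    def test_batch_size_independence(self, halfplane_grid_provider):
        cfg = TrackingConfig(h=0.1, max_steps=60)
        seeds = self._seeds()
        full = trace_batch(seeds, cfg, halfplane_grid_provider)
        chunked = []
        for i in range(0, len(seeds), 7):
            chunked.extend(trace_batch(seeds[i : i + 7], cfg, halfplane_grid_provider))
        for a, b in zip(full, chunked):
            np.testing.assert_array_equal(a.points, b.points)

    def test_rerun_determinism_bitwise(self, halfplane_grid_provider):
        cfg = TrackingConfig(h=0.1, max_steps=60)
        seeds = self._seeds()
        a = trace_batch(seeds, cfg, halfplane_grid_provider)
        b = trace_batch(seeds, cfg, halfplane_grid_provider)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.points, fb.points)

    def test_empty_seed_list(self, halfplane_grid_provider):
        assert trace_batch([], TrackingConfig(), halfplane_grid_provider) == []

    def test_invalid_seed_yields_error_record(self, halfplane_grid_provider):
        cfg = TrackingConfig(h=0.1, max_steps=10)
        seeds = [([32.0, 15.0, 4.0], [1.0, 0, 0]), ([-9.0, 0, 0], [1.0, 0, 0])]
        fibers = trace_batch(seeds, cfg, halfplane_grid_provider)
        assert len(fibers) == 2
        assert fibers[0].termination == "max_steps"
        assert fibers[1].termination == "error" and fibers[1].error

    @pytest.mark.parametrize("solver", ["euler", "rk2"])
    def test_straight_line_on_constant_field(self, solver):
        """On any constant SPD field the geodesic is an exact line."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=(3, 3))
        sym = (a @ a.T + np.eye(3))[np.triu_indices(3)]
        provider = ConstantFieldProvider(sym)
        cfg = TrackingConfig(h=0.1, max_steps=1000, solver=solver)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        fiber = trace_fiber([0.0, 0.0, 0.0], d, cfg, provider)
        assert fiber.termination == "max_steps"
        expected_end = 1000 * 0.1 * d
        assert np.linalg.norm(fiber.points[-1] - expected_end) <= 1e-6


class TestTraceStreamline:
    def test_homogeneous_matches_geodesic(self):
        vol = make_homogeneous((64, 16, 16), (9, 1, 1), (1, 0, 0))
        fields = precompute(vol)
        cfg = TrackingConfig(h=0.1, max_steps=100)
        stream = trace_streamline([5.0, 8.0, 8.0], cfg, vol)
        geo = trace_fiber([5.0, 8.0, 8.0], [1.0, 0, 0], cfg, GridFieldProvider(fields))
        n = min(stream.n_points, geo.n_points)
        np.testing.assert_allclose(stream.points[:n], geo.points[:n], atol=1e-9)

    def test_reference_direction_sets_sign(self):
        vol = make_homogeneous((64, 16, 16), (9, 1, 1), (1, 0, 0))
        cfg = TrackingConfig(h=0.1, max_steps=30)
        fiber = trace_streamline([40.0, 8.0, 8.0], cfg, vol, reference_direction=[-1, 0, 0])
        assert fiber.points[-1][0] < 40.0 - 2.9
        np.testing.assert_allclose(fiber.points[:, 1], 8.0, atol=1e-9)

    def test_curved_phantom_follows_circle(self):
        """The tangential eigenvector field keeps the streamline within
        one voxel of its circle over a quarter turn."""
        vol = make_curved((64, 64, 8), radius=20.0)
        cfg = TrackingConfig(h=0.05, max_steps=round(0.25 * 2 * np.pi * 20 / 0.05))
        cx = cy = 31.5
        fiber = trace_streamline([cx + 20.0, cy, 4.0], cfg, vol, reference_direction=[0, 1, 0])
        r = np.hypot(fiber.points[:, 0] - cx, fiber.points[:, 1] - cy)
        assert np.abs(r - 20.0).max() < 1.0
        turn = np.unwrap(np.arctan2(fiber.points[:, 1] - cy, fiber.points[:, 0] - cx))
        assert turn[-1] - turn[0] >= 0.9 * (np.pi / 2)

    def test_isotropic_seed_without_reference_is_degenerate(self):
        vol = make_homogeneous((8, 8, 8), (1, 1, 1), (1, 0, 0))
        with pytest.raises(DegenerateDirectionError):
            trace_streamline([4.0, 4.0, 4.0], TrackingConfig(), vol)

    def test_separated_from_geodesic_on_halfplane(self, halfplane_grid_provider):
        """The two trackers solve different ODEs: on the half-plane the
        geodesic bends onto a semicircle while the streamline does not."""
        vol = make_halfplane((64, 64, 8), y0=1.0)
        cfg = TrackingConfig(h=0.05, max_steps=1000)
        geo = trace_fiber([32.0, 15.0, 4.0], [1.0, 0, 0], cfg, halfplane_grid_provider)
        stream = trace_streamline([32.0, 15.0, 4.0], cfg, vol, reference_direction=[1, 0, 0])
        n = min(geo.n_points, stream.n_points)
        assert np.max(np.linalg.norm(geo.points[:n] - stream.points[:n], axis=1)) > 5.0
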