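"""Per-voxel objective/minimizer and the ICM denoising loop."""

import numpy as np
import pytest

import mridenoise as md
from mridenoise.prior import update_voxel_hyperparameters
from mridenoise.solver import global_objective
from mridenoise.volume import ImageStack, NeighborhoodSystem


def grid_search_minimum(ak, sigma, neighbor_values, pair_weights, n=100_000):
    """Dense-grid oracle for the per-voxel minimizer on (0, ak)."""
    bs = np.linspace(ak / n, ak * (1 - 1.0 / n), n)
    t = ak - bs
    obj = -np.log(t / sigma**2) + t**2 / (2 * sigma**2)
    for v, w in zip(neighbor_values, pair_weights):
        obj = obj + 2.0 * w * (bs - v) ** 2
    return bs[np.argmin(obj)]


class TestVoxelObjective:
    def test_likelihood_only_value_at_minimizer(self):
        # at b = a - sigma the likelihood terms evaluate to log(sigma) + 1/2
        ak, sigma = 12.0, 3.0
        val = md.voxel_objective(ak - sigma, ak, sigma, [], [])
        assert val == pytest.approx(np.log(sigma) + 0.5, rel=1e-12)

    def test_barrier_at_right_endpoint(self):
        ak, sigma = 10.0, 1.0
        near = md.voxel_objective(ak - 1e-13, ak, sigma, [], [])
        assert near > md.voxel_objective(ak - 1.0, ak, sigma, [], [])
        assert md.voxel_objective(ak, ak, sigma, [], []) == np.inf
        assert md.voxel_objective(0.0, ak, sigma, [], []) == np.inf
        assert md.voxel_objective(-1.0, ak, sigma, [], []) == np.inf

    def test_prior_term_vanishes_when_neighbors_equal(self):
        ak, sigma, bk = 10.0, 1.0, 6.0
        with_prior = md.voxel_objective(bk, ak, sigma, [bk, bk, bk], [1.0, 2.0, 3.0])
        without = md.voxel_objective(bk, ak, sigma, [], [])
        assert with_prior == pytest.approx(without, rel=1e-12)


class TestMinimizeVoxel:
    def test_prior_free_closed_form(self):
        for ak, sigma in [(10.0, 1.0), (50.0, 4.0), (3.0, 2.0)]:
            assert md.minimize_voxel(ak, sigma, [], []) == pytest.approx(
                ak - sigma, abs=1e-8
            )

    def test_prior_dominated_limit(self):
        # enormous weights pull the solution onto the neighbor value
        ak, sigma, v = 20.0, 2.0, 7.0
        b = md.minimize_voxel(ak, sigma, [v] * 4, [1e9] * 4)
        assert b == pytest.approx(v, abs=1e-4)

    def test_agrees_with_grid_search(self, rng):
        for _ in range(50):
            ak = float(rng.uniform(5, 50))
            sigma = float(rng.uniform(0.5, 8))
            nn = int(rng.integers(0, 8))
            vals = rng.uniform(0, ak, nn).tolist()
            ws = rng.uniform(1e-3, 2.0, nn).tolist()
            b_star = md.minimize_voxel(ak, sigma, vals, ws)
            b_grid = grid_search_minimum(ak, sigma, vals, ws)
            assert abs(b_star - b_grid) < 2 * ak / 100_000
            # the closed form can never do worse than the grid point
            assert md.voxel_objective(b_star, ak, sigma, vals, ws) <= md.voxel_objective(
                b_grid, ak, sigma, vals, ws
            ) + 1e-12

    def test_degenerate_ak_clamped(self):
        assert 0 < md.minimize_voxel(0.0, 1.0, [], []) < 1e-6
        assert md.minimize_voxel(-1.0, 1.0, [], []) > 0

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            md.minimize_voxel(5.0, -1.0, [], [])


def _random_problem(rng, dims=(8, 8, 8), sigma=2.0):
    truth = rng.uniform(10, 60, dims)
    a = ImageStack(truth + sigma * np.sqrt(-2 * np.log(1 - rng.random(dims))), (1, 1, 1))
    nsys = NeighborhoodSystem.for_stack(a)
    b0 = ImageStack(np.clip(a.values - sigma, 1e-9, None), (1, 1, 1))
    h = update_voxel_hyperparameters(b0, nsys)
    return a, b0, h, nsys, sigma


class TestIcmSweep:
    @pytest.mark.parametrize("order", ["checkerboard", "raster"])
    def test_objective_non_increasing(self, rng, order):
        cfg = md.SolverConfig(sweep_order=order)
        for _ in range(10):
            a, b, h, nsys, sigma = _random_problem(rng)
            prev = global_objective(b, a, sigma, h, nsys)
            for _sweep in range(3):
                b = md.icm_sweep(b, a, sigma, h, nsys, cfg)
                cur = global_objective(b, a, sigma, h, nsys)
                assert cur <= prev + 1e-9 * abs(prev)
                prev = cur

    def test_fixed_point(self, rng):
        a, b, h, nsys, sigma = _random_problem(rng)
        for _ in range(60):
            b = md.icm_sweep(b, a, sigma, h, nsys)
        again = md.icm_sweep(b, a, sigma, h, nsys)
        np.testing.assert_allclose(again.values, b.values, atol=1e-7)

    def test_raster_and_checkerboard_both_reduce(self, rng):
        a, b, h, nsys, sigma = _random_problem(rng, dims=(6, 6, 6))
        before = global_objective(b, a, sigma, h, nsys)
        for order in ("checkerboard", "raster"):
            out = md.icm_sweep(b, a, sigma, h, nsys, md.SolverConfig(sweep_order=order))
            assert global_objective(out, a, sigma, h, nsys) <= before + 1e-9 * abs(before)


class TestRunMapDenoise:
    def test_flat_input_prior_free_solution(self):
        sigma = 1e-6  # noise floor so the input is effectively noiseless
        a = md.add_noise(ImageStack(np.full((8, 8, 8), 30.0), (1, 1, 1)), sigma, seed=1)
        res = md.run_map_denoise(a, 2.0)
        # flat field: every voxel ends at ~a - sigma, itself flat
        np.testing.assert_allclose(res.b_hat.values, 28.0, atol=1e-3)
        assert np.ptp(res.b_hat.values) < 1e-3

    def test_improves_masked_mse(self, small_denoise):
        truth, noisy, mask, res = small_denoise
        assert md.mse(res.b_hat, truth, mask) < md.mse(noisy, truth, mask)

    def test_constraints_and_diagnostics(self, small_denoise):
        _, noisy, _, res = small_denoise
        assert np.all(res.b_hat.values > 0)
        assert np.all(res.b_hat.values < noisy.values)
        assert res.iterations_run == len(res.mean_correction_trace)
        assert all(np.isfinite(c) and c >= 0 for c in res.mean_correction_trace)
        assert res.converged
        d = res.diagnostics()
        assert d["iterations_run"] == res.iterations_run

    def test_correction_trace_falls_below_threshold(self, small_denoise):
        *_, res = small_denoise
        assert res.mean_correction_trace[-1] < 1e-3

    def test_deterministic(self, small_phantom):
        _, noisy, _ = small_phantom
        cfg = md.SolverConfig(max_outer_iterations=3)
        r1 = md.run_map_denoise(noisy, 4.0, cfg)
        r2 = md.run_map_denoise(noisy, 4.0, cfg)
        assert np.array_equal(r1.b_hat.values, r2.b_hat.values)
        assert r1.mean_correction_trace == r2.mean_correction_trace

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.full((4, 4, 4), np.inf), (1, 1, 1))

    def test_reduced_neighborhood_accepted(self, small_phantom):
        truth, noisy, mask = small_phantom
        cfg = md.SolverConfig(neighborhood=6, max_outer_iterations=5)
        res = md.run_map_denoise(noisy, 4.0, cfg)
        assert md.mse(res.b_hat, truth, mask) < md.mse(noisy, truth, mask)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            md.SolverConfig(max_outer_iterations=0)
        with pytest.raises(ValueError):
            md.SolverConfig(correction_threshold=0)
        with pytest.raises(ValueError):
            md.SolverConfig(sweep_order="spiral")
        with pytest.raises(ValueError):
            md.SolverConfig(neighborhood=5)
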