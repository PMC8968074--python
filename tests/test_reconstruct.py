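"""Optimizer components: TV prox, Adam/Nesterov step, batching, recovery."""

import numpy as np
import pytest

import speckletomo as st
from speckletomo.forward import ForwardConfig, forward_image
from speckletomo.reconstruct import (
    OptimizerState,
    ReconConfig,
    adam_nesterov_step,
    run_reconstruction,
    sample_minibatch,
    tv1d_prox,
)
from speckletomo.transport import DetectorGrid, SourceSpec, bin_detectors, simulate


def tv_objective(x, y, gamma):
    return 0.5 * np.sum((x - y) ** 2) + gamma * np.sum(np.abs(np.diff(x)))


class TestTvProx:
    def test_gamma_zero_is_identity(self):
        y = np.array([3.0, -1.0, 2.5])
        assert np.array_equal(tv1d_prox(y, 0.0), y)

    def test_constant_vector_unchanged(self):
        y = np.full(7, 2.2)
        assert np.allclose(tv1d_prox(y, 5.0), y)

    def test_two_point_closed_form(self):
        # interior stationarity at step gamma toward each other
        assert tv1d_prox(np.array([0.0, 1.0]), 0.25) == pytest.approx([0.25, 0.75])

    def test_never_increases_objective(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y = rng.normal(0, 2, rng.integers(2, 40))
            gamma = rng.uniform(0, 2)
            x = tv1d_prox(y, gamma)
            assert tv_objective(x, y, gamma) <= tv_objective(y, y, gamma) + 1e-12

    def test_matches_exact_dual_solution(self):
        # oracle: x = y - D^T z* with z* the box-constrained least-squares dual
        from scipy.optimize import lsq_linear

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 25))
            y = rng.normal(0, 2, n)
            gamma = rng.uniform(0.01, 1.5)
            D = np.diff(np.eye(n), axis=0)
            z = lsq_linear(D.T, y, bounds=(-gamma, gamma), tol=1e-14).x
            assert np.allclose(tv1d_prox(y, gamma), y - D.T @ z, atol=1e-8)

    def test_large_gamma_flattens_to_mean(self):
        y = np.array([1.0, 5.0, 3.0, 4.0])
        assert np.allclose(tv1d_prox(y, 100.0), y.mean())


class TestAdamNesterovStep:
    def _cfg(self, **kw):
        return ReconConfig(**kw)

    def test_zero_gradient_leaves_iterate_fixed(self):
        state = OptimizerState.initial(4, 1.0)
        cfg = self._cfg(gamma=0.0)
        out = adam_nesterov_step(state, np.zeros(4), cfg, k=1)
        assert np.array_equal(out.V, state.V)

    def test_tiny_eta_leaves_iterate_nearly_fixed(self):
        state = OptimizerState.initial(4, 1.0)
        cfg = self._cfg(eta=1e-15, gamma=0.0)
        out = adam_nesterov_step(state, np.ones(4), cfg, k=1)
        assert np.allclose(out.V, state.V, atol=1e-12)

    def test_first_step_has_no_acceleration(self):
        # t0 = 1 so the extrapolation coefficient (t0-1)/t1 vanishes at k=1
        state = OptimizerState.initial(3, 1.0)
        cfg = self._cfg(gamma=0.0, nesterov_cap=1.0)
        out = adam_nesterov_step(state, np.array([1.0, -1.0, 0.5]), cfg, k=1)
        # without acceleration the result equals the prox output exactly
        assert np.array_equal(out.V, out.V_prox_prev)

    def test_t_sequence_follows_golden_recursion(self):
        state = OptimizerState.initial(2, 1.0)
        out = adam_nesterov_step(state, np.ones(2), self._cfg(), k=1)
        assert out.t_k == pytest.approx(0.5 * (1 + np.sqrt(5)))  # ~1.6180
        out2 = adam_nesterov_step(out, np.ones(2), self._cfg(), k=2)
        assert out2.t_k == pytest.approx(0.5 * (1 + np.sqrt(1 + 4 * out.t_k**2)))

    def test_positivity_enforced(self):
        state = OptimizerState.initial(3, 0.01)
        cfg = self._cfg(eta=10.0, gamma=0.0)
        out = adam_nesterov_step(state, np.ones(3), cfg, k=1)
        assert np.all(out.V >= 0.0)

    def test_nonfinite_gradient_aborts(self):
        state = OptimizerState.initial(2, 1.0)
        with pytest.raises(FloatingPointError):
            adam_nesterov_step(state, np.array([np.nan, 0.0]), self._cfg(), k=1)

    def test_adam_moments_use_bias_correction(self):
        # after one step from zero moments, m_hat equals the raw gradient
        state = OptimizerState.initial(1, 1.0)
        cfg = self._cfg(gamma=0.0, eta=0.1)
        g = np.array([2.0])
        out = adam_nesterov_step(state, g, cfg, k=1)
        # V <- V - eta * m_hat / (sqrt(v_hat) + eps) with m_hat = g, v_hat = g^2
        expected = 1.0 - 0.1 * 2.0 / (2.0 + cfg.eps)
        assert out.V[0] == pytest.approx(expected)


class TestSampleMinibatch:
    def test_full_fraction_without_replacement_is_identity(self):
        ids = sample_minibatch(10, 1.0, seed=0, k=1, with_replacement=False)
        assert sorted(ids) == list(range(10))

    def test_deterministic_for_fixed_seed_and_iteration(self):
        a = sample_minibatch(8000, 0.125, seed=42, k=7)
        b = sample_minibatch(8000, 0.125, seed=42, k=7)
        assert np.array_equal(a, b)
        c = sample_minibatch(8000, 0.125, seed=42, k=8)
        assert not np.array_equal(a, c)

    def test_with_replacement_draws_expected_count(self):
        ids = sample_minibatch(8000, 0.125, seed=1, k=1)
        assert len(ids) == 1000
        # replacement: duplicates are possible and expected at this size
        assert len(np.unique(sample_minibatch(100, 1.0, seed=2, k=3))) < 100


@pytest.fixture(scope="module")
def toy_inversion(small_phantom):
    """Identical-trajectory toy problem: measured images from the same MC set."""
    geometry, strands = small_phantom
    truth = st.assign_flows(strands, "uniform_random", lo=0.3, hi=5.0, seed=21)
    grid = DetectorGrid(n=40, pixel_size=15.0, center=(300, 300),
                        aperture_radius=300.0)
    sources = [
        bin_detectors(
            simulate(geometry, strands, SourceSpec(position=p, source_id=i), 400_000, seed=50 + i),
            grid,
        )
        for i, p in enumerate([(150, 150), (450, 450)])
    ]
    fwd = ForwardConfig()
    images = [forward_image(b, truth, fwd) for b in sources]
    return sources, images, strands, truth, fwd


class TestRunReconstruction:
    def test_truth_is_fixed_point_with_identical_trajectories(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        cfg = ReconConfig(N_iter=5, gamma=0.0, seed=1)
        flows, trace = run_reconstruction(
            sources, images, strands, cfg, fwd, truth=truth, v0=truth
        )
        assert np.array_equal(flows.vector(truth.group_ids), truth.v)
        assert trace["batch_cost"].iloc[-1] == 0.0

    def test_cost_decreases_in_full_batch_mode(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        cfg = ReconConfig(N_iter=20, batch_fraction=1.0, with_replacement=False, seed=2)
        _, trace = run_reconstruction(sources, images, strands, cfg, fwd)
        costs = trace["batch_cost"].to_numpy()
        assert costs[-1] < costs[0]

    def test_toy_recovery_converges_to_truth(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        cfg = ReconConfig(N_iter=120, batch_fraction=1.0, with_replacement=False, seed=3)
        flows, trace = run_reconstruction(sources, images, strands, cfg, fwd, truth=truth)
        assert trace["median_error_pct"].iloc[-1] < 2.0

    def test_large_gamma_flattens_reconstruction(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        cfg = ReconConfig(N_iter=30, gamma=50.0, seed=4)
        flows, _ = run_reconstruction(sources, images, strands, cfg, fwd)
        assert np.ptp(flows.v) < 0.2 * max(np.ptp(truth.v), 1e-9)

    def test_batch_seeds_agree_within_noise(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        outs = []
        for seed in (5, 6):
            cfg = ReconConfig(N_iter=80, seed=seed)
            flows, _ = run_reconstruction(sources, images, strands, cfg, fwd)
            outs.append(flows.v)
        assert np.median(np.abs(outs[0] - outs[1]) / np.maximum(outs[0], 0.1)) < 0.25

    def test_mismatched_images_rejected(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        with pytest.raises(ValueError):
            run_reconstruction(sources, images[:1], strands, ReconConfig(), fwd)

    def test_positivity_throughout(self, toy_inversion):
        sources, images, strands, truth, fwd = toy_inversion
        cfg = ReconConfig(N_iter=40, seed=7)
        flows, _ = run_reconstruction(sources, images, strands, cfg, fwd)
        assert np.all(flows.v >= 0.0)
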