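import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bifmem as bm
from bifmem.dynamics import DEFAULT_GAIN


def mattis_matrix(xi: np.ndarray) -> np.ndarray:
    J = np.outer(xi, xi).astype(float) / xi.shape[0]
    np.fill_diagonal(J, 0.0)
    return J


class TestNeuralField:
    def test_zero_coupling_zero_input_is_pure_decay(self):
        x = np.linspace(-1, 1, 7)
        dx = bm.neural_field(x, np.zeros((7, 7)))
        np.testing.assert_allclose(dx, -x)

    def test_input_only_drive(self):
        eta = np.array([1.0, -1.0, 1.0])
        dx = bm.neural_field(np.zeros(3), np.zeros((3, 3)), eta, gamma=1.0)
        np.testing.assert_allclose(dx, np.tanh(DEFAULT_GAIN * eta))

    def test_mattis_matrix_field_along_target(self):
        N = 20
        xi = np.ones(N)
        xi[::2] = -1
        dx = bm.neural_field(xi, mattis_matrix(xi))
        expected = (np.tanh(DEFAULT_GAIN * (1 - 1 / N)) - 1) * xi
        np.testing.assert_allclose(dx, expected, atol=1e-12)
        # one common sign factor relative to the target
        np.testing.assert_allclose(dx / xi, dx[0] / xi[0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bm.neural_field(np.zeros(3), np.zeros((4, 4)))


class TestSimulate:
    def test_linear_decay_with_zero_coupling(self):
        x0 = np.array([0.9, -0.5, 0.3])
        params = bm.DynamicsParams(dt=0.01, t_transient=0, t_measure=5)
        traj = bm.simulate(x0, np.zeros((3, 3)), params=params)
        T = traj.times[-1]
        assert np.linalg.norm(traj.states[-1]) <= np.linalg.norm(x0) * np.exp(-T) + 10 * params.dt

    def test_determinism_bit_identical(self, r_one_step_net):
        x0 = bm.initial_state(100, rng=0)
        params = bm.DynamicsParams(dt=0.01, t_transient=0, t_measure=5)
        a = bm.simulate(x0, r_one_step_net.J, params=params)
        b = bm.simulate(x0, r_one_step_net.J, params=params)
        assert np.array_equal(a.states, b.states)

    def test_state_confinement(self, r_one_step_net):
        x0 = bm.initial_state(100, rng=3)
        params = bm.DynamicsParams(dt=0.1, t_transient=0, t_measure=50)
        traj = bm.simulate(x0, r_one_step_net.J, params=params)
        assert np.all(np.abs(traj.states) <= 1 + 1e-12)

    def test_step_halving_consistency(self, r_one_step_net):
        x0 = bm.initial_state(100, rng=7)
        J = r_one_step_net.J
        dt = 0.02
        a = bm.simulate(x0, J, params=bm.DynamicsParams(dt=dt, t_transient=0, t_measure=10, record_stride=1))
        b = bm.simulate(x0, J, params=bm.DynamicsParams(dt=dt / 2, t_transient=0, t_measure=10, record_stride=2))
        err = np.max(np.abs(a.states[-1] - b.states[-1]))
        assert err < 10 * dt

    def test_agrees_with_adaptive_integrator(self):
        # explicit Euler vs scipy RK45 on a small random instance
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(2)
        N = 10
        J = rng.normal(0, 1 / np.sqrt(N), (N, N))
        np.fill_diagonal(J, 0)
        x0 = rng.uniform(-1, 1, N)
        dt = 0.01
        traj = bm.simulate(x0, J, params=bm.DynamicsParams(dt=dt, t_transient=0, t_measure=10))
        sol = solve_ivp(
            lambda t, x: bm.neural_field(x, J),
            (0, 10), x0, rtol=1e-9, atol=1e-11,
        )
        assert np.max(np.abs(traj.states[-1] - sol.y[:, -1])) < 10 * dt

    def test_fixed_point_residual(self, nr_one_step_net):
        # evoked NR dynamics converge to a fixed point of the flow
        net = nr_one_step_net
        m = net.mapping_set.mappings[0]
        x0 = m.target.astype(float) * 0.9
        traj = bm.simulate(
            x0, net.J, m.input, bm.DynamicsParams(gamma_recall=1.0, t_transient=0, t_measure=200)
        )
        residual = bm.neural_field(traj.states[-1], net.J, m.input, gamma=1.0)
        assert np.max(np.abs(residual)) < 1e-6

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_odd_symmetry(self, seed):
        # negating the state and the input negates the whole trajectory
        rng = np.random.default_rng(seed)
        N = 12
        J = rng.normal(0, 0.5, (N, N))
        np.fill_diagonal(J, 0)
        x0 = rng.uniform(-1, 1, N)
        eta = rng.choice([-1.0, 1.0], N)
        params = bm.DynamicsParams(gamma_recall=2.0, dt=0.02, t_transient=0, t_measure=5)
        a = bm.simulate(x0, J, eta, params)
        b = bm.simulate(-x0, J, -eta, params)
        np.testing.assert_allclose(b.states, -a.states, atol=1e-12)

    def test_mean_states_matches_trajectory_average(self):
        rng = np.random.default_rng(4)
        N = 10
        J = rng.normal(0, 0.4, (N, N))
        np.fill_diagonal(J, 0)
        x0 = rng.uniform(-1, 1, N)
        params = bm.DynamicsParams(dt=0.01, t_transient=1, t_measure=5, record_stride=1)
        traj = bm.simulate(x0, J, params=params)
        _, mean = bm.simulate_mean_states(x0[:, None], J, None, params)
        post = traj.states[traj.times > params.t_transient]
        np.testing.assert_allclose(mean[:, 0], post.mean(axis=0), atol=1e-8)


class TestOverlap:
    def test_identity_and_reversal(self):
        xi = np.array([1.0, -1.0, 1.0, 1.0])
        assert bm.overlap(xi, xi) == pytest.approx(1.0)
        assert bm.overlap(-xi, xi) == pytest.approx(-1.0)

    def test_orthogonal_pattern(self):
        p = np.ones(10)
        x = np.ones(10) * 0.5
        x[:5] *= -1
        assert bm.overlap(x, p) == pytest.approx(0.0)

    def test_series_oddness_and_constant(self):
        times = np.linspace(0, 1, 11)
        xi = np.array([1.0, -1.0])
        traj = bm.Trajectory(times=times, states=np.tile(xi, (11, 1)))
        s = bm.overlap_series(traj, xi)
        np.testing.assert_allclose(s.values, 1.0)
        neg = bm.overlap_series(bm.Trajectory(times=times, states=-traj.states), xi)
        np.testing.assert_allclose(neg.values, -s.values)
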