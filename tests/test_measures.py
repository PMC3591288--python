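import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bifmem as bm
from bifmem.dynamics import DEFAULT_GAIN
from bifmem.measures import _capacity_from_D


def make_network(J, n_mappings=1, seed=3):
    """Wrap an explicit connection matrix in a TrainedNetwork shell."""
    ms = bm.generate_mapping_set(J.shape[0], n_mappings, seed=seed)
    return bm.TrainedNetwork(
        J=J,
        mapping_set=ms,
        params=bm.LearningParams(gamma_learn=16, epsilon=0.01),
        records=(),
        seed=seed,
    )


class TestTimeStats:
    def test_constant_series(self):
        s = bm.OverlapSeries(times=np.linspace(0, 1, 9), values=np.full(9, 0.4))
        assert bm.time_stats(s) == (pytest.approx(0.4), pytest.approx(0.0))

    def test_alternating_series(self):
        v = np.tile([0.3, -0.3], 10)
        s = bm.OverlapSeries(times=np.arange(20.0), values=v)
        mean, sd = bm.time_stats(s)
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(0.3)

    def test_empty_window_rejected(self):
        s = bm.OverlapSeries(times=np.arange(5.0), values=np.zeros(5))
        with pytest.raises(ValueError):
            bm.time_stats(s, t_transient=10.0)


class TestProjections:
    def test_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            J = rng.normal(size=(10, 10))
            a = rng.choice([-1.0, 1.0], 10)
            b = rng.choice([-1.0, 1.0], 10)
            brute = sum(
                a[i] * J[i, j] * b[j] for i in range(10) for j in range(10)
            ) / 10
            assert abs(bm.project(J, a, b) - brute) < 1e-12

    def test_mattis_projection(self):
        N = 20
        xi = np.ones(N)
        xi[5:] = -1
        J = np.outer(xi, xi) / N
        np.fill_diagonal(J, 0)
        assert bm.project(J, xi, xi) == pytest.approx(1 - 1 / N)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        J1, J2 = rng.normal(size=(2, 8, 8))
        a = rng.choice([-1.0, 1.0], 8)
        b = rng.choice([-1.0, 1.0], 8)
        assert bm.project(J1 + J2, a, b) == pytest.approx(
            bm.project(J1, a, b) + bm.project(J2, a, b)
        )

    def test_random_matrix_projection_small(self):
        # c of a random ±1/sqrt(N) matrix has SD 1/sqrt(N): 5 sigma bound
        N = 100
        count = 0
        trials = 200
        for s in range(trials):
            J = bm.initial_connections(N, rng=s)
            ms = bm.generate_mapping_set(N, 1, seed=s + 1000)
            c = bm.project(J, ms.mappings[0].target, ms.mappings[0].input)
            count += abs(c) < 5 / np.sqrt(N)
        assert count / trials >= 0.99

    def test_quad_vs_age_matches_matrix_quad(self, small_net):
        quads = bm.quad_vs_age(small_net, M=3)
        q1 = bm.matrix_quad(small_net.J, small_net.mapping_set.by_age(1))
        assert quads[0] == q1
        assert len(quads) == 3


class TestRecallAndD:
    def test_mattis_fixed_point_overlap(self):
        # single-pattern Mattis matrix: from x0 = target at gamma 0 the
        # overlap settles at the root of m = S(m (1 - 1/N))
        from scipy.optimize import brentq

        N = 100
        ms = bm.generate_mapping_set(N, 1, seed=2)
        xi = ms.mappings[0].target.astype(float)
        J = np.outer(xi, xi) / N
        np.fill_diagonal(J, 0)
        traj = bm.simulate(
            xi, J, params=bm.DynamicsParams(t_transient=50, t_measure=100)
        )
        series = bm.overlap_series(traj, xi)
        mean, sd = bm.time_stats(series, t_transient=50)
        m_star = brentq(
            lambda m: np.tanh(DEFAULT_GAIN * m * (1 - 1 / N)) - m, 0.5, 1.0
        )
        assert sd < 1e-8
        assert mean == pytest.approx(m_star, abs=1e-3)

    def test_zero_coupling_network_has_negative_D(self):
        # with J = 0 the evoked state is S(gamma eta): the input overlap is
        # near 1 and the target overlap is a random cross-overlap
        net = make_network(np.zeros((100, 100)))
        D = bm.overlap_difference(net, 1, gamma_r=16.0)
        assert D < 0
        res = bm.recall_trial(net, 1, gamma_r=16.0)
        assert not res.success
        assert res.mean_input_overlap > 0.9

    def test_recall_success_in_r_regime_latest(self, r_one_step_net):
        res = bm.recall_trial(r_one_step_net, 1)
        assert res.success
        assert res.mean_target_overlap > 0.9
        # success means strict maximum over the whole competitor set
        assert res.mean_target_overlap > res.best_competitor_overlap

    def test_unknown_age_rejected(self, small_net):
        with pytest.raises(IndexError):
            bm.recall_trial(small_net, 99)


class TestCapacity:
    def test_capacity_from_D_definition(self):
        assert _capacity_from_D(np.array([0.5, 0.3, 0.005, 0.4]), 0.01) == 2
        assert _capacity_from_D(np.array([0.005, 0.5]), 0.01) == 0
        assert _capacity_from_D(np.array([0.5, 0.4, 0.3]), 0.01) == 3

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        d=st.lists(st.floats(-1, 1), min_size=1, max_size=30),
        t1=st.floats(0.001, 0.2),
        t2=st.floats(0.001, 0.2),
    )
    def test_theta_monotonicity(self, d, t1, t2):
        lo, hi = sorted((t1, t2))
        D = np.array(d)
        assert _capacity_from_D(D, hi) <= _capacity_from_D(D, lo)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            bm.capacity([])


class TestSpontaneousStats:
    def test_quiescent_network_has_zero_sd(self):
        # J = 0: spontaneous activity decays to the origin
        net = make_network(np.zeros((50, 50)), n_mappings=2)
        st_ = bm.spontaneous_stats(net, M=2)
        assert np.all(st_.sd < 1e-6)
        assert st_.probe_sd < 1e-6

    def test_window_validation(self, small_net):
        with pytest.raises(ValueError):
            bm.spontaneous_stats(small_net, M=99)


class TestDecayFit:
    def test_exact_power_law(self):
        mus = np.arange(1, 31)
        fit = bm.fit_decay_exponent(mus.astype(float) ** -0.5)
        assert fit.exponent == pytest.approx(0.5, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        alpha=st.floats(0.1, 2.0),
        c=st.floats(0.1, 10.0),
        seed=st.integers(0, 1000),
    )
    def test_noisy_power_law_recovery(self, alpha, c, seed):
        rng = np.random.default_rng(seed)
        mus = np.arange(1, 31)
        vals = c * mus.astype(float) ** -alpha * (1 + rng.uniform(-0.01, 0.01, 30))
        fit = bm.fit_decay_exponent(vals)
        assert fit.exponent == pytest.approx(alpha, abs=0.05)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            bm.fit_decay_exponent([1.0, 0.0, 0.5])

    def test_fit_range(self):
        mus = np.arange(1, 21).astype(float)
        vals = mus**-1.0
        vals[10:] = 1.0  # corrupt the tail
        fit = bm.fit_decay_exponent(vals, mu_range=(1, 10))
        assert fit.exponent == pytest.approx(1.0, abs=1e-12)
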