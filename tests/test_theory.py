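"""Unit tests for the analytic fixed points and the TD correspondence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procode.theory import (
    ConvergenceError,
    MarkovEnvironment,
    TDParams,
    discount_operator,
    discount_operator_series,
    effective_discount,
    fourier_fixed_point,
    markov_fixed_point,
    markov_fixed_point_series,
    mean_ode_trajectory,
    periodic_fixed_point,
    td1_equivalence_check,
    td_lambda_learn,
    value_function,
)


def random_env(seed, n=5, n_syn=None, lam=0.8, gamma=0.3):
    rng = np.random.default_rng(seed)
    T = rng.random((n, n)) + 0.05
    T /= T.sum(axis=1, keepdims=True)
    n_syn = n_syn or n + 2
    B = rng.random((n, n_syn)) + 0.1
    r_I = rng.random(n) * 0.05
    return MarkovEnvironment(T=T, B=B, r_I=r_I, lam=lam, gamma=gamma)


class TestPeriodicFixedPoint:
    def test_zero_input_zero_output(self):
        g = np.zeros(1000)
        assert np.all(periodic_fixed_point(g, 1.0, 0.9, 9.0, 100.0, 0.1) == 0)
        assert np.all(fourier_fixed_point(g, 1.0, 0.9, 9.0, 100.0) == 0)

    def test_constant_input_closed_form(self):
        g = np.full(2000, 0.02)
        f = periodic_fixed_point(g, 1.0, 0.9, 9.0, 200.0, 0.1)
        assert np.allclose(f, 0.9 * 0.02 / (1 - 0.9), rtol=1e-6)
        fh = fourier_fixed_point(g, 1.0, 0.9, 9.0, 200.0)
        assert np.allclose(fh, 0.9 * 0.02 / (1 - 0.9), rtol=1e-12)

    def test_time_domain_matches_fourier_route(self):
        # independent oracle: per-mode solution vs wrapped convolution
        period, dt = 500.0, 0.01
        n = int(period / dt)
        t = np.arange(n) * dt
        w = 2 * np.pi / period
        g = 0.03 * (1 + 0.5 * np.sin(w * t) + 0.3 * np.cos(2 * w * t))
        f_time = periodic_fixed_point(g, 1.0, 0.9, 9.0, period, dt)
        f_four = fourier_fixed_point(g, 1.0, 0.9, 9.0, period)
        assert np.max(np.abs(f_time - f_four)) < 1e-7

    def test_high_modes_attenuated(self):
        period = 1000.0
        n = 10000
        t = np.arange(n) * (period / n)
        w = 2 * np.pi / period
        for k in (1, 3, 7):
            g = 0.01 * (1 + np.cos(k * w * t))
            f = fourier_fixed_point(g, 1.0, 0.9, 9.0, period)
            fh = np.fft.fft(f)
            gain_0 = np.abs(fh[0]) / np.abs(np.fft.fft(g)[0])
            gain_k = np.abs(fh[k]) / np.abs(np.fft.fft(g)[k])
            assert gain_k < gain_0

    def test_divergent_tau_eff_raises(self):
        with pytest.raises(ValueError):
            periodic_fixed_point(np.ones(100), 1.0, 1.0, 9.0, 10.0, 0.1)


class TestDiscountOperator:
    def test_gamma_zero_is_scaled_identity(self):
        env = random_env(0, gamma=0.0)
        assert np.allclose(discount_operator(env, 0.7), 0.7 * np.eye(env.n_states))

    def test_row_sums(self):
        env = random_env(1, gamma=0.4)
        A = discount_operator(env, 0.55)
        assert np.allclose(A.sum(axis=1), 0.55 / (1 - 0.4), atol=1e-10)

    def test_uniform_two_state_by_hand(self):
        env = MarkovEnvironment(
            T=[[0.5, 0.5], [0.5, 0.5]], B=np.eye(2), r_I=[0.0, 0.0],
            lam=0.5, gamma=0.5,
        )
        A = discount_operator(env, 1.0)
        assert np.allclose(A, [[1.5, 0.5], [0.5, 1.5]])

    def test_solve_matches_truncated_series(self):
        env = random_env(2, gamma=0.6)
        assert np.allclose(
            discount_operator(env, 0.3), discount_operator_series(env, 0.3),
            atol=1e-10,
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_contraction_in_pi_weighted_norm(self, seed):
        # row sums below 1 make A a contraction wrt <x,y> = x' Pi y
        rng = np.random.default_rng(seed)
        env = random_env(seed, n=int(rng.integers(2, 7)), gamma=0.3)
        alpha = 0.6  # row sums = 0.6/0.7 < 1
        A = discount_operator(env, alpha)
        Pi = np.diag(env.pi)
        z = rng.normal(size=env.n_states)
        norm = lambda x: np.sqrt(x @ Pi @ x)
        assert norm(A @ z) <= norm(z) + 1e-12


class TestMarkovFixedPoint:
    def test_lam_zero_reduces_to_discounted_input(self):
        env = random_env(3, lam=0.0, gamma=0.4)
        rv = markov_fixed_point(env, 0.5)
        assert np.allclose(rv, discount_operator(env, 0.5) @ env.r_I)

    def test_deterministic_two_cycle_by_hand(self):
        env = MarkovEnvironment(
            T=[[0.0, 1.0], [1.0, 0.0]], B=np.eye(2), r_I=[1.0, 0.0],
            lam=0.0, gamma=0.5,
        )
        assert np.allclose(markov_fixed_point(env, 1.0), [4.0 / 3.0, 2.0 / 3.0])

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_solve_and_series_forms_agree(self, seed):
        env = random_env(seed, n=5, lam=0.8, gamma=0.3)
        alpha = 0.6  # lam*alpha = 0.48 < 0.7 = 1 - gamma
        assert np.allclose(
            markov_fixed_point(env, alpha), markov_fixed_point_series(env, alpha),
            atol=1e-9,
        )

    def test_convergence_condition_enforced(self):
        env = random_env(4, lam=1.0, gamma=0.5)
        with pytest.raises(ConvergenceError):
            markov_fixed_point(env, 0.6)  # lam*alpha = 0.6 > 0.5 = 1-gamma

    def test_gamma_eff_monotone_to_one(self):
        lam, gamma = 0.9, 0.4
        alphas = np.linspace(0.0, (1 - gamma) / lam - 1e-4, 30)
        geffs = [effective_discount(gamma, lam, a) for a in alphas]
        assert np.all(np.diff(geffs) > 0)
        assert geffs[-1] > 0.99
        assert geffs[0] == pytest.approx(gamma)

    def test_matches_periodic_fixed_point_on_deterministic_cycle(self):
        # an N-cycle chain with step delta = dt is the discrete version
        # of a periodic environment.  The discrete eligibility trace
        # sum_s gamma^s PSP lacks the 1/tau kernel normalisation, so the
        # continuous potentiation factor alpha maps to the per-step
        # factor alpha_d = 1 - exp(-lam*alpha*dt/tau), which makes
        # gamma/(1-lam*alpha_d) = exp(-dt/tau_eff) exactly
        dt = 0.1
        n = 2000  # period 200 ms
        tau, lam, alpha = 9.0, 1.0, 0.9
        gamma = np.exp(-dt / tau)
        alpha_d = (1.0 - np.exp(-lam * alpha * dt / tau)) / lam
        T = np.roll(np.eye(n), 1, axis=1)
        t = np.arange(n) * dt
        g = 0.02 * (1 + 0.6 * np.sin(2 * np.pi * t / 200.0))
        env = MarkovEnvironment(T=T, B=np.eye(n)[:, :1], r_I=g, lam=lam, gamma=gamma)
        g_eff = effective_discount(gamma, lam, alpha_d)
        assert g_eff == pytest.approx(
            np.exp(-dt / (tau / (1 - lam * alpha))), rel=1e-10
        )
        rv = markov_fixed_point(env, alpha_d)
        f = periodic_fixed_point(g, lam, alpha, tau, 200.0, dt)
        assert np.allclose(rv, f, rtol=0.02)


class TestMeanODE:
    def test_lyapunov_non_increasing_and_converges(self):
        env = random_env(10, n=4, n_syn=6, lam=0.8, gamma=0.3)
        alpha = 0.6
        traj, L, w_star = mean_ode_trajectory(
            env, alpha, eta=1.0, w0=np.zeros(6), n_steps=4000
        )
        assert np.all(np.diff(L) <= 1e-12)
        rv = env.B @ traj[-1]
        assert np.allclose(rv, markov_fixed_point(env, alpha), atol=1e-6)

    def test_zero_input_relaxes_to_zero_rate(self):
        env = random_env(11, n=3, n_syn=5, lam=0.8, gamma=0.3)
        env.r_I = np.zeros(env.n_states)
        traj, _, _ = mean_ode_trajectory(
            env, 0.6, eta=1.0, w0=np.ones(5), n_steps=6000
        )
        assert np.allclose(env.B @ traj[-1], 0.0, atol=1e-6)

    def test_divergent_step_raises(self):
        env = random_env(12, n=3, n_syn=4)
        with pytest.raises(ConvergenceError):
            mean_ode_trajectory(
                env, 0.6, eta=1.0, w0=np.zeros(4), n_steps=2000, step=1e6
            )

    def test_affine_transfer_shifts_fixed_point(self):
        # with phi(u) = a u + c the fixed point becomes
        # r_V = (I - lam A)^{-1} A (r_I - lam c)
        env = random_env(13, n=4, n_syn=6, lam=0.8, gamma=0.3)
        alpha, c = 0.6, 0.01
        traj, _, _ = mean_ode_trajectory(
            env, alpha, eta=1.0, w0=np.zeros(6), n_steps=60000,
            phi_slope=1.0, phi_intercept=c,
        )
        rv = env.B @ traj[-1] + c
        A = discount_operator(env, alpha)
        n = env.n_states
        expected = np.linalg.solve(
            np.eye(n) - env.lam * A, A @ (env.r_I - env.lam * c)
        )
        assert np.allclose(rv, expected, atol=1e-6)


class TestTDCorrespondence:
    def test_value_function_zero_input(self):
        env = random_env(20)
        td = TDParams(gamma_TD=0.7)
        env.r_I = np.zeros(env.n_states)
        assert np.allclose(value_function(env, 0.6, td), 0.0)

    def test_one_state_geometric_series(self):
        env = MarkovEnvironment(T=[[1.0]], B=[[1.0]], r_I=[0.04], lam=0.5, gamma=0.2)
        td = TDParams(gamma_TD=0.8)
        expected = (0.6 / (1 - 0.6 * 0.5)) * 0.04 / (1 - 0.8)
        assert value_function(env, 0.6, td)[0] == pytest.approx(expected)

    def test_gamma_eff_makes_value_equal_fixed_point(self):
        env = random_env(21, lam=0.8, gamma=0.3)
        alpha = 0.6
        g_eff = effective_discount(env.gamma, env.lam, alpha)
        V = value_function(env, alpha, TDParams(gamma_TD=g_eff))
        assert np.allclose(V, markov_fixed_point(env, alpha), atol=1e-9)

    def test_delta_error_zero_at_value_function(self):
        env = random_env(22, n=3, n_syn=3, lam=0.8, gamma=0.3)
        env.B = np.eye(3)
        alpha = 0.6
        g_eff = effective_discount(env.gamma, env.lam, alpha)
        td = TDParams(gamma_TD=g_eff, lambda_TD=0.5, eta=1e-12)
        w0 = value_function(env, alpha, td)
        _, deltas = td_lambda_learn(env, alpha, td, seed=5, n_steps=10000, w0=w0)
        sem = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 3 * sem + 1e-12

    def test_learning_converges_to_value_function(self):
        env = random_env(23, n=3, n_syn=3, lam=0.8, gamma=0.3)
        env.B = np.eye(3)
        alpha = 0.6
        g_eff = effective_discount(env.gamma, env.lam, alpha)
        td = TDParams(gamma_TD=g_eff, lambda_TD=env.gamma / g_eff, eta=0.02)
        traj, _ = td_lambda_learn(env, alpha, td, seed=6, n_steps=200000,
                                  record_every=100)
        V = value_function(env, alpha, td)
        estimate = traj[len(traj) // 2:].mean(axis=0)
        assert np.max(np.abs(estimate - V)) / np.max(np.abs(V)) < 0.05

    def test_eligibility_trace_equals_lowpass_psp_trace(self):
        # lambda_TD * gamma_TD = gamma makes the TD trace recursion
        # identical to the rule's low-pass PSP recursion
        env = random_env(24, n=4, lam=0.8, gamma=0.3)
        alpha = 0.6
        g_eff = effective_discount(env.gamma, env.lam, alpha)
        lam_td = env.gamma / g_eff
        rng = np.random.default_rng(0)
        states = rng.integers(0, env.n_states, size=200)
        e = np.zeros(env.n_synapses)
        p_tilde = np.zeros(env.n_synapses)
        for x in states:
            e = lam_td * g_eff * e + env.B[x]
            p_tilde = env.gamma * p_tilde + env.B[x]
            assert np.allclose(e, p_tilde, atol=1e-12)

    def test_td1_single_step_identity(self):
        # delta_t PSPtilde_t expands into the potentiation/depression
        # terms plus a telescoping pair, via gamma PSPtilde_t =
        # PSPtilde_{t+1} - PSP_{t+1}
        rng = np.random.default_rng(7)
        env = random_env(25, n=4, lam=0.8, gamma=0.3)
        alpha = 0.6
        for _ in range(20):
            x, x1 = rng.integers(0, env.n_states, size=2)
            w = rng.normal(size=env.n_synapses)
            p_tilde = rng.random(env.n_synapses)
            v = env.B @ w
            r_u = env.lam * v[x] + env.r_I[x]
            p_tilde_next = env.gamma * p_tilde + env.B[x1]
            delta = alpha * r_u + env.gamma * v[x1] - v[x]
            lhs = delta * p_tilde
            rule_terms = alpha * r_u * p_tilde - v[x1] * env.B[x1]
            telescoping = v[x1] * p_tilde_next - v[x] * p_tilde
            assert np.allclose(lhs, rule_terms + telescoping, atol=1e-12)

    def test_td1_discrepancy_linear_in_eta(self):
        env = random_env(26, n=4, lam=0.8, gamma=0.3)
        alpha = 0.6
        d0 = td1_equivalence_check(env, alpha, seed=3, n_steps=2000, eta=0.0)
        d1 = td1_equivalence_check(env, alpha, seed=3, n_steps=2000, eta=0.01)
        d2 = td1_equivalence_check(env, alpha, seed=3, n_steps=2000, eta=0.005)
        assert d0 == 0.0
        assert d1 / d2 == pytest.approx(2.0, rel=0.25)


class TestEnvironmentValidation:
    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            MarkovEnvironment(T=[[0.5, 0.4], [0.5, 0.5]], B=np.eye(2),
                              r_I=[0.0, 0.0])

    def test_stationary_distribution_validated(self):
        env = random_env(30)
        assert np.allclose(env.pi @ env.T, env.pi, atol=1e-10)
        assert np.all(env.pi > 0)
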