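"""Unit tests for the two-compartment neuron model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from procode.core_model import (
    ConductanceSchedule,
    NeuronParams,
    SpikeTrainSet,
    StabilityError,
    compute_traces,
    dendritic_potential,
    firing_rate,
    integrate_soma,
    psp_kernel,
    psp_traces,
    sample_spikes,
    steady_state_decomposition,
)


class TestPspKernel:
    def test_negative_times_are_zero(self, neuron):
        assert psp_kernel(-1.0, neuron) == 0.0
        assert np.all(psp_kernel(np.array([-5.0, -0.1]), neuron) == 0.0)

    def test_normalisation_by_quadrature(self, neuron):
        integral, err = quad(lambda t: psp_kernel(t, neuron), 0, 200)
        assert integral == pytest.approx(1.0, abs=1e-6)
        # closed form: 1/c = tau_m - tau_s = 20/3 ms
        assert neuron.kappa_norm == pytest.approx(3.0 / 20.0)

    def test_argmax_matches_closed_form(self, neuron):
        t = np.arange(0, 50, 1e-4)
        t_peak_grid = t[np.argmax(psp_kernel(t, neuron))]
        tm, ts = neuron.tau_m, neuron.tau_s
        t_peak = tm * ts * np.log(tm / ts) / (tm - ts)
        assert t_peak == pytest.approx(5.493, abs=1e-3)
        assert t_peak_grid == pytest.approx(t_peak, abs=1e-3)

    def test_nonnegative_and_unimodal(self, neuron):
        t = np.arange(0, 100, 0.01)
        k = psp_kernel(t, neuron)
        assert np.all(k >= 0)
        d = np.diff(k)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes <= 1


class TestSpikeTrains:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([[5.0, 3.0]], duration=10.0)
        with pytest.raises(ValueError):
            SpikeTrainSet([[11.0]], duration=10.0)
        with pytest.raises(ValueError):
            SpikeTrainSet([[-0.5]], duration=10.0)

    def test_psp_trace_matches_explicit_convolution(self, neuron):
        dt = 0.1
        spikes = SpikeTrainSet([[5.0], [2.0, 40.0]], duration=100.0)
        traces = psp_traces(spikes, dt, neuron)
        t = np.arange(int(100 / dt)) * dt
        # spikes snapped to bin-left; kernel evaluated at t - t_spike
        expected0 = psp_kernel(t - 5.0, neuron)
        expected1 = psp_kernel(t - 2.0, neuron) + psp_kernel(t - 40.0, neuron)
        assert np.allclose(traces[0], expected0, atol=1e-12)
        assert np.allclose(traces[1], expected1, atol=1e-12)

    def test_periodic_wrap_carries_psp_across_boundary(self, neuron):
        dt = 0.1
        # spike just before the period end must shape the next period start
        spikes = SpikeTrainSet([[195.0]], duration=200.0, periodic=True)
        tr = psp_traces(spikes, dt, neuron)
        assert tr[0, 0] > 0.01  # 5 ms after the spike, near the kernel peak
        # and equals the infinite-sum value of repeated periods
        t_after = 5.0
        expected = sum(psp_kernel(t_after + k * 200.0, neuron) for k in range(10))
        assert tr[0, 0] == pytest.approx(expected, rel=1e-10)


class TestDendriticPotential:
    def test_zero_weights_give_zero(self, neuron):
        spikes = SpikeTrainSet([[1.0], [2.0]], duration=50.0)
        v = dendritic_potential([0.0, 0.0], spikes, 0.1, neuron)
        assert np.all(v == 0)

    def test_single_spike_reproduces_kernel(self, neuron):
        spikes = SpikeTrainSet([[10.0]], duration=100.0)
        v = dendritic_potential([1.0], spikes, 0.1, neuron)
        t = np.arange(1000) * 0.1
        assert np.allclose(v, psp_kernel(t - 10.0, neuron), atol=1e-12)

    def test_length_mismatch_raises(self, neuron):
        spikes = SpikeTrainSet([[1.0]], duration=10.0)
        with pytest.raises(ValueError):
            dendritic_potential([1.0, 2.0], spikes, 0.1, neuron)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_linearity_in_weights(self, neuron, scale, seed):
        rng = np.random.default_rng(seed)
        spikes = SpikeTrainSet(
            [np.sort(rng.uniform(0, 50, size=3)) for _ in range(4)], duration=50.0
        )
        w = rng.normal(size=4)
        v1 = dendritic_potential(w, spikes, 0.1, neuron)
        v2 = dendritic_potential(scale * w, spikes, 0.1, neuron)
        assert np.allclose(v2, scale * v1, rtol=1e-12, atol=1e-12)


class TestIntegrateSoma:
    def test_homogeneous_decay_time_constant(self, neuron):
        # with no input, U decays with time constant C/(g_L+g_D) = 0.526 ms
        dt = 0.001
        n = 3000
        sched = ConductanceSchedule.zeros(n, dt)
        U = integrate_soma(neuron, np.zeros(n), sched, dt, U0=1.0)
        t = np.arange(n) * dt
        tau_expected = neuron.cap_ms / (neuron.g_L + neuron.g_D)
        assert tau_expected == pytest.approx(0.5263, abs=1e-3)
        slope = np.polyfit(t[100:2000], np.log(U[100:2000]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau_expected, rel=1e-2)

    def test_constant_dendrite_fixed_point(self, neuron):
        dt = 0.1
        n = 2000
        v = 0.5
        sched = ConductanceSchedule.zeros(n, dt)
        U = integrate_soma(neuron, np.full(n, v), sched, dt)
        expected = neuron.g_D * v / (neuron.g_L + neuron.g_D)
        assert U[-1] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1800.0 / 1900.0 * v)

    def test_constant_conductances_reach_steady_state(self, neuron):
        dt = 0.1
        n = 2000
        v = 0.3
        sched = ConductanceSchedule(np.full(n, 15.0), np.full(n, 2.0), dt)
        U = integrate_soma(neuron, np.full(n, v), sched, dt)
        _, _, _, U_expected = steady_state_decomposition(v, 15.0, 2.0, neuron)
        assert U[-1] == pytest.approx(float(U_expected), rel=1e-9)

    def test_unstable_step_raises(self, neuron):
        sched = ConductanceSchedule(np.full(10, 1e5), np.zeros(10), 0.1)
        with pytest.raises(StabilityError):
            integrate_soma(neuron, np.zeros(10), sched, 0.1)

    def test_quasi_static_agreement_with_decomposition(self, neuron):
        # piecewise-constant conductances, held >> C/g_tot: after each
        # transient the Euler trajectory matches lam*V* + U* within 2%
        dt = 0.01
        seg = int(50.0 / dt)  # 50 ms >> 0.5 ms relaxation
        gE = np.concatenate([np.full(seg, g) for g in (0.0, 10.0, 30.0, 5.0)])
        sched = ConductanceSchedule(gE, np.zeros_like(gE), dt)
        V_w = np.full(gE.size, 0.4)
        U = integrate_soma(neuron, V_w, sched, dt)
        _, _, _, U_approx = steady_state_decomposition(V_w, gE, 0.0, neuron)
        for s in range(4):
            tail = slice((s + 1) * seg - seg // 5, (s + 1) * seg)
            assert np.allclose(U[tail], U_approx[tail], rtol=0.02)


class TestDecomposition:
    def test_no_somatic_input_gives_unit_nudging(self, neuron):
        lam, _, _, U = steady_state_decomposition(0.0, 0.0, 0.0, neuron)
        assert lam == 1.0
        assert U == 0.0

    def test_pulse_values(self, neuron):
        lam, _, U_star, _ = steady_state_decomposition(0.0, 15.0, 0.0, neuron)
        assert lam == pytest.approx(1900.0 / 1915.0)
        assert U_star == pytest.approx(70.0 / 1915.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(gE=st.floats(0, 1e4), gI=st.floats(0, 1e4), v=st.floats(-2, 2))
    def test_nudging_factor_in_unit_interval(self, neuron, gE, gI, v):
        lam, _, _, _ = steady_state_decomposition(v, gE, gI, neuron)
        assert 0.0 < lam <= 1.0


class TestFiringRate:
    @pytest.mark.parametrize(
        "U,expected", [(0.5, 0.03), (-0.2, 0.0), (2.0, 0.06), (0.0, 0.0), (1.0, 0.06)]
    )
    def test_transfer_function(self, neuron, U, expected):
        assert firing_rate(U, neuron) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(U=st.floats(-10, 10))
    def test_rates_bounded(self, neuron, U):
        r = firing_rate(U, neuron)
        assert 0.0 <= r <= neuron.phi_max


class TestSampleSpikes:
    def test_zero_rate_yields_no_spikes(self):
        assert sample_spikes(np.zeros(1000), 0.1, 0).size == 0

    def test_count_matches_binomial_statistics(self):
        rate, dt, n = 0.06, 0.1, 10**6
        times = sample_spikes(np.full(n, rate), dt, seed=7)
        mean = n * rate * dt
        sd = np.sqrt(n * rate * dt * (1 - rate * dt))
        assert abs(times.size - mean) < 5 * sd

    def test_seed_determinism(self):
        r = np.full(5000, 0.05)
        assert np.array_equal(sample_spikes(r, 0.1, 3), sample_spikes(r, 0.1, 3))

    def test_probability_overflow_raises(self):
        with pytest.raises(ValueError):
            sample_spikes(np.full(10, 20.0), 0.1, 0)


class TestTraceBundle:
    def test_compute_traces_consistency(self, neuron):
        dt = 0.1
        n = 1000
        V_w = 0.3 * np.sin(np.arange(n) * dt / 20.0) ** 2
        sched = ConductanceSchedule(np.full(n, 5.0), np.zeros(n), dt)
        tb = compute_traces(V_w, sched, neuron, dt)
        assert np.all(tb.lam > 0) and np.all(tb.lam <= 1)
        assert np.all(tb.rate_U >= 0) and np.all(tb.rate_U <= neuron.phi_max)
        assert tb.to_frame().shape == (n, 8)
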