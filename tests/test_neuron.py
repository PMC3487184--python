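import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trisyn import _kernels
from trisyn.config import NeuronConfig
from trisyn.errors import InvalidParameterError
from trisyn.neuron import (HHState, detect_spikes, estimate_rate, hh_step,
                           mean_rate, resting_state, simulate_hh)

P = NeuronConfig()


def _reference_trajectory(I, t_eval, state):
    """Adaptive high-accuracy integration of the same HH vector field."""

    def rhs(t, y):
        return _kernels.hh_deriv(y[0], y[1], y[2], y[3], I, P.C, P.g_na, P.g_k,
                                 P.g_l, P.e_na, P.e_k, P.e_l)

    sol = solve_ivp(rhs, (0, t_eval[-1]), [state.V, state.m, state.h, state.n],
                    t_eval=t_eval, rtol=1e-10, atol=1e-12, method="RK45")
    return sol.y[0]


class TestRestingBehavior:
    def test_rest_is_quiescent_and_stable(self):
        rest = resting_state()
        t, V = simulate_hh(0.0, 500.0, dt=0.01)
        assert detect_spikes(V, 0.01).size == 0
        assert np.all(np.abs(V - rest.V) < 1.0)

    def test_resting_potential_near_minus_65(self):
        assert resting_state().V == pytest.approx(-65.0, abs=1.5)


class TestIntegrationAccuracy:
    def test_rk4_matches_adaptive_reference_subthreshold(self):
        """Fixed-step RK4 vs adaptive solver: < 0.1 mV RMS over 100 ms."""
        state = resting_state()
        t, V = simulate_hh(3.0, 100.0, dt=0.01, state=state)
        V_ref = _reference_trajectory(3.0, t, state)
        rms = np.sqrt(np.mean((V - V_ref) ** 2))
        assert rms < 0.1

    def test_suprathreshold_spiking_with_overshoot(self):
        t, V = simulate_hh(10.0, 500.0, dt=0.01)
        spikes = detect_spikes(V, 0.01)
        assert spikes.size >= 20  # sustained periodic firing
        assert V.max() > 0.0  # positive overshoot
        isi = np.diff(spikes)
        assert isi.std() / isi.mean() < 0.02  # periodic

    def test_spike_times_converge_when_dt_halved(self):
        _, V1 = simulate_hh(10.0, 100.0, dt=0.01)
        _, V2 = simulate_hh(10.0, 100.0, dt=0.005)
        s1 = detect_spikes(V1, 0.01)
        s2 = detect_spikes(V2, 0.005)
        n = min(s1.size, s2.size)
        assert n >= 4
        assert np.max(np.abs(s1[:n] - s2[:n])) < 0.05

    def test_fi_curve_nondecreasing(self):
        rates = []
        for I in np.arange(0.0, 21.0, 4.0):
            _, V = simulate_hh(I, 600.0, dt=0.02)
            spikes = detect_spikes(V, 0.02)
            rates.append(mean_rate(spikes, 600.0, transient=100.0))
        assert np.all(np.diff(rates) >= -1e-12)

    def test_gating_bounded_under_random_input(self):
        rng = np.random.default_rng(8)
        s = resting_state()
        for _ in range(20_000):
            s = hh_step(s, rng.uniform(-5.0, 25.0), P, 0.02)
            assert 0.0 <= s.m <= 1.0 and 0.0 <= s.h <= 1.0 and 0.0 <= s.n <= 1.0

    def test_oversized_dt_rejected(self):
        with pytest.raises(InvalidParameterError):
            hh_step(HHState(), 0.0, P, 0.1)


class TestSpikeDetection:
    def test_flat_trace_empty(self):
        V = np.full(1000, -65.0)
        assert detect_spikes(V, 0.1).size == 0

    def test_three_synthetic_spikes(self):
        from trisyn.fixtures import synthetic_hh_trace

        t, V = synthetic_hh_trace(n_spikes=3, duration=100.0, dt=0.1)
        times = detect_spikes(V, 0.1)
        assert times.size == 3
        assert np.allclose(times, [25.0, 50.0, 75.0], atol=0.6)

    def test_double_crossing_within_refractory_counted_once(self):
        dt = 0.1
        V = np.full(100, -65.0)
        V[20:23] = 10.0  # first crossing at 2.0 ms
        V[25:28] = 10.0  # second crossing 0.5 ms later, inside 2-ms dead time
        assert detect_spikes(V, dt, refractory=2.0).size == 1

    def test_refractory_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            detect_spikes(np.zeros(10), 0.1, refractory=0.0)


class TestRateEstimation:
    def test_count_over_window(self):
        spikes = np.linspace(0, 999, 30)
        t, r = estimate_rate(spikes, 1000.0, window=1000.0, stride=100.0)
        assert r[-1] == pytest.approx(0.03)

    def test_empty_train_zero(self):
        t, r = estimate_rate(np.array([]), 2000.0, window=1000.0)
        assert np.all(r == 0)

    def test_periodic_train_constant_rate(self):
        spikes = np.arange(5.0, 5000.0, 10.0)  # 100 Hz
        t, r = estimate_rate(spikes, 5000.0, window=1000.0, stride=100.0)
        assert np.allclose(r, 0.1)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_rate(np.array([1.0]), 500.0, window=1000.0)
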