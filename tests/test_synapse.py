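import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from trisyn.errors import InvalidParameterError
from trisyn.synapse import (amplitude_cdf, amplitude_mean, amplitude_pdf,
                            dendritic_gate, release_increment,
                            sample_epsc_amplitude, step_epsc,
                            step_neurotransmitter, synaptic_current)


def _random_pulse_schedule(rng, total=1000.0):
    """Random alternating off/on segments (duration, pulse_on) summing to total."""
    segs, t = [], 0.0
    on = False
    while t < total:
        d = rng.uniform(0.5, 40.0)
        segs.append((min(d, total - t), on))
        t += d
        on = not on
    return segs


class TestNeurotransmitter:
    def test_free_decay_closed_form(self):
        X, dt = 1.5, 0.01
        for _ in range(1000):
            X = step_neurotransmitter(X, False, 2.0, 0.1, dt)
        assert X == pytest.approx(1.5 * np.exp(-0.1 * 10.0), rel=1e-9)

    def test_held_pulse_saturates_at_release_efficacy(self):
        X = 0.0
        for _ in range(20_000):
            X = step_neurotransmitter(X, True, 2.0, 0.1, 0.01)
        assert X == pytest.approx(2.0, abs=1e-6)

    def test_depressed_efficacy_scales_asymptote(self):
        # k_pre = k0*(1+gamma1*Y1) = 2*(1-0.8) = 0.4 at full astro activation
        X = 0.0
        for _ in range(20_000):
            X = step_neurotransmitter(X, True, 2.0 * (1 - 0.8), 0.1, 0.01)
        assert X == pytest.approx(0.4, abs=1e-6)

    def test_stepped_update_matches_segmentwise_closed_form(self):
        """Exact-exponential stepping composes to the closed form on any
        piecewise-constant pulse schedule (relative error < 1e-6)."""
        rng = np.random.default_rng(0)
        alpha_x, k_pre, dt = 0.1, 2.0, 0.01
        for _ in range(5):
            X_step = X_exact = 0.3
            for dur, on in _random_pulse_schedule(rng):
                n = int(round(dur / dt))
                for _ in range(n):
                    X_step = step_neurotransmitter(X_step, on, k_pre, alpha_x, dt)
                target = k_pre if on else 0.0
                X_exact = target + (X_exact - target) * np.exp(-alpha_x * n * dt)
                assert X_step == pytest.approx(X_exact, rel=1e-6)

    def test_release_increment_values(self):
        assert release_increment(0.0, 2.0, 0.1) == pytest.approx(0.2)
        assert release_increment(2.0, 2.0, 0.1) == 0.0
        assert release_increment(1.0, 2.0, 0.1) == pytest.approx(0.1)


class TestAmplitudeLaw:
    def test_density_normalizes_to_one(self):
        for b in (5.0, 25.0, 50.0):
            integral, err = integrate.quad(lambda a: amplitude_pdf(a, b), 0, np.inf)
            assert abs(integral - 1.0) < 1e-10

    def test_cdf_closed_form_at_scale(self):
        assert amplitude_cdf(5.0, 5.0) == pytest.approx(1 - np.exp(-1))

    def test_sampler_mean_matches_analytic_moment(self, rng):
        b = 5.0
        draws = sample_epsc_amplitude(b, rng, size=1_000_000)
        assert amplitude_mean(b) == pytest.approx(b * np.sqrt(np.pi) / 2)
        assert abs(draws.mean() - amplitude_mean(b)) < 0.002 * b

    def test_sampler_distribution_matches_cdf(self, rng):
        b = 7.0
        draws = np.sort(sample_epsc_amplitude(b, rng, size=20_000))
        ecdf = np.arange(1, draws.size + 1) / draws.size
        sup = np.max(np.abs(ecdf - amplitude_cdf(draws, b)))
        assert sup < 0.015

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            sample_epsc_amplitude(0.0, rng)


class TestEpsc:
    def test_free_decay(self):
        I = 3.0
        for _ in range(500):
            I = step_epsc(I, False, 10.0, 0.1, 0.01)
        assert I == pytest.approx(3.0 * np.exp(-0.5), rel=1e-9)

    def test_one_ms_pulse_step_response(self):
        # From rest, a 1-ms pulse charges to A*(1 - exp(-alpha_i * 1 ms)).
        I, A = 0.0, 4.0
        for _ in range(100):
            I = step_epsc(I, True, A, 0.1, 0.01)
        assert I == pytest.approx(A * (1 - np.exp(-0.1)), rel=1e-9)

    def test_held_pulse_fixed_point_is_amplitude(self):
        I, A = 0.0, 2.5
        for _ in range(30_000):
            I = step_epsc(I, True, A, 0.1, 0.01)
        assert I == pytest.approx(A, abs=1e-9)


class TestGateAndCurrent:
    def test_gate_midpoint_and_saturation(self):
        assert dendritic_gate(0.2, 0.2, 0.05) == pytest.approx(0.5)
        assert dendritic_gate(100.0, 0.2, 0.05) == pytest.approx(1.0)
        assert dendritic_gate(-100.0, 0.2, 0.05) == pytest.approx(0.0)
        assert dendritic_gate(0.25, 0.2, 0.05) == pytest.approx(1 / (1 + np.e**-1))

    @given(st.floats(-1, 3), st.floats(-1, 3))
    def test_gate_monotone(self, x1, x2):
        """Nondecreasing everywhere; strictly increasing away from the
        floating-point-saturated tails."""
        lo, hi = sorted((x1, x2))
        g_lo, g_hi = dendritic_gate(lo, 0.2, 0.05), dendritic_gate(hi, 0.2, 0.05)
        assert g_lo <= g_hi
        if hi - lo > 1e-9 and -0.4 <= lo and hi <= 0.8:
            assert g_lo < g_hi

    def test_synaptic_current_products(self):
        assert synaptic_current(10.0, 0.0) == 0.0
        assert synaptic_current(0.0, 0.7) == 0.0
        assert synaptic_current(10.0, 0.5, g_syn=1.0) == pytest.approx(5.0)
        with pytest.raises(InvalidParameterError):
            synaptic_current(1.0, 1.2)


class TestTemporalSummation:
    def test_x_bounded_by_release_efficacy(self):
        rng = np.random.default_rng(3)
        k_pre = 2.0
        X = 0.0
        for _ in range(2000):
            X = step_neurotransmitter(X, bool(rng.random() < 0.3), k_pre, 0.1, 0.1)
            assert 0.0 <= X <= k_pre

    def test_mean_x_increases_with_input_rate(self):
        """Temporal summation: the time-averaged neurotransmitter level grows
        with the Poisson input rate."""
        from trisyn.stimulus import generate_poisson_train, pulses_from_events

        means = []
        for f_in in (0.05, 0.2, 0.5):
            vals = []
            for seed in range(3):
                train = generate_poisson_train(f_in, 4000.0, seed=seed)
                sig = pulses_from_events(train, tau=1.0, dt=0.05)
                X, acc = 0.0, 0.0
                for on in sig.samples:
                    X = step_neurotransmitter(X, bool(on), 2.0, 0.1, 0.05)
                    acc += X
                vals.append(acc / sig.samples.size)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
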