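import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trisyn.errors import ComparisonError, FitError, InvalidParameterError
from trisyn.experiments import (QParams, compare_conditions, fit_logistic,
                                presyn_suppression_curve, scan_io_curve,
                                steady_states)
from trisyn.fixtures import synthetic_logistic_curve


class TestLogisticFit:
    def test_recovers_noiseless_parameters(self):
        x, y = synthetic_logistic_curve(L=0.1, x0=0.2, s=0.05, n=20)
        q = fit_logistic((x, y))
        assert q.L == pytest.approx(0.1, rel=0.01)
        assert q.x0 == pytest.approx(0.2, rel=0.01)
        assert q.s == pytest.approx(0.05, rel=0.01)
        assert q.residual_rms < 1e-6

    def test_degenerate_data_raise(self):
        x = np.linspace(0, 0.5, 10)
        with pytest.raises(FitError):
            fit_logistic((x, np.zeros(10)))
        with pytest.raises(FitError):
            fit_logistic((x[:4], np.linspace(0, 1, 4)))

    def test_noisy_recovery_within_three_se(self):
        """Additive noise at 5% of the ceiling, 100 replicates: the mean
        fitted parameters land within 3 SEs of the generating values."""
        rng = np.random.default_rng(11)
        truth = dict(L=0.1, x0=0.2, s=0.05)
        fits = []
        for _ in range(100):
            x, y = synthetic_logistic_curve(**truth, n=20)
            q = fit_logistic((x, y + 0.05 * truth["L"] * rng.standard_normal(y.size)))
            fits.append((q.L, q.x0, q.s))
        fits = np.array(fits)
        for i, key in enumerate(("L", "x0", "s")):
            se = fits[:, i].std(ddof=1) / np.sqrt(len(fits))
            assert abs(fits[:, i].mean() - truth[key]) < 3 * se


class TestSteadyStates:
    Q = QParams(L=0.1, x0=0.2, s=0.03, floor=0.0)

    def test_zero_gain_single_stable_point_at_f0(self):
        ss = steady_states(self.Q, 0.0, 0.025)
        assert len(ss.points) == 1
        p = ss.points[0]
        assert p.stable and p.f == pytest.approx(0.025, abs=1e-9)

    def test_low_regime_single_stable_point(self):
        ss = steady_states(self.Q, 0.5, 0.02)
        assert ss.regime == "low" and len(ss.stable_points) == 1

    def test_bistable_regime_three_roots_middle_unstable(self):
        ss = steady_states(self.Q, 3.0, 0.04)
        assert len(ss.points) == 3
        stable_flags = [p.stable for p in ss.points]
        assert stable_flags == [True, False, True]
        assert ss.regime == "bistable"
        # Dense-grid sign-change oracle on g(f) = f0 + kN*Q(f) - f.
        f = np.linspace(0, 0.5, 200_001)
        g = 0.04 + 3.0 * self.Q(f) - f
        oracle_roots = f[:-1][np.sign(g[:-1]) * np.sign(g[1:]) < 0]
        assert len(oracle_roots) == 3
        np.testing.assert_allclose([p.f for p in ss.points], oracle_roots, atol=1e-5)

    def test_unstable_root_separates_basins_of_the_rate_map(self):
        """Map-level oracle: trajectories of df/dt = (f0 + kN*Q(f) - f)/tau
        started just above/below the middle root diverge to the outer roots."""
        ss = steady_states(self.Q, 3.0, 0.04)
        lo, mid, hi = [p.f for p in ss.points]

        def rhs(t, y):
            return (0.04 + 3.0 * self.Q(y[0]) - y[0]) / 10.0

        up = solve_ivp(rhs, (0, 5000), [mid + 1e-4], rtol=1e-8).y[0, -1]
        down = solve_ivp(rhs, (0, 5000), [mid - 1e-4], rtol=1e-8).y[0, -1]
        assert up == pytest.approx(hi, abs=1e-4)
        assert down == pytest.approx(lo, abs=1e-4)

    def test_invalid_gain_rejected(self):
        with pytest.raises(InvalidParameterError):
            steady_states(self.Q, -1.0, 0.02)


class TestIOCurveScan:
    def test_deterministic_and_zero_at_zero_input(self, control_cfg):
        grid = np.array([0.0, 0.3])
        a = scan_io_curve(grid, 2, control_cfg, seed=1, duration=2000.0)
        b = scan_io_curve(grid, 2, control_cfg, seed=1, duration=2000.0)
        np.testing.assert_array_equal(a.f_out, b.f_out)
        assert a.f_out[0].max() == 0.0  # no input events, no spikes
        assert a.f_out[1].min() > 0.0

    def test_rejects_empty_grid(self, control_cfg):
        with pytest.raises(InvalidParameterError):
            scan_io_curve([], 2, control_cfg)


class TestCompareConditions:
    def test_identical_conditions_give_exact_zero(self, control_cfg):
        grid = np.array([0.2, 0.4])
        a = scan_io_curve(grid, 3, control_cfg, seed=2, duration=2000.0)
        b = scan_io_curve(grid, 3, control_cfg, seed=2, duration=2000.0)
        table = compare_conditions(a, b)
        assert np.all(table.delta_f_out_khz == 0.0)
        assert list(table.label) == ["unchanged", "unchanged"]

    def test_grid_mismatch_rejected(self, control_cfg):
        a = scan_io_curve(np.array([0.2, 0.4]), 2, control_cfg, seed=2, duration=2000.0)
        b = scan_io_curve(np.array([0.2, 0.5]), 2, control_cfg, seed=2, duration=2000.0)
        with pytest.raises(ComparisonError):
            compare_conditions(a, b)

    def test_seed_mismatch_rejected(self, control_cfg):
        grid = np.array([0.2])
        a = scan_io_curve(grid, 2, control_cfg, seed=2, duration=2000.0)
        b = scan_io_curve(grid, 2, control_cfg, seed=3, duration=2000.0)
        with pytest.raises(ComparisonError):
            compare_conditions(a, b)


class TestScanDeterminism:
    def test_bifurcation_scan_reproducible_end_to_end(self, control_cfg):
        """A reduced-budget dual-initialization scan run twice with one seed
        yields identical converged rates (end-to-end determinism)."""
        from trisyn.experiments import bifurcation_scan

        cfg = control_cfg.with_overrides({"network": {"f0": 0.07}})
        kw = dict(seeds=[5, 6], f_init_low=0.0, f_init_high=0.4, duration=6000.0)
        a = bifurcation_scan("k_n", [3.0, 8.0], cfg, **kw)
        b = bifurcation_scan("k_n", [3.0, 8.0], cfg, **kw)
        np.testing.assert_array_equal(a.low_rates, b.low_rates)
        np.testing.assert_array_equal(a.high_rates, b.high_rates)


class TestPresynapticSuppression:
    def test_depression_gain_lowers_network_rate(self, control_cfg):
        """In a network-driven state, increasing presynaptic depression pulls
        the firing rate down toward the spontaneous floor."""
        cfg = control_cfg.with_overrides(
            {"astrocyte": {"gamma2": 0.0}, "network": {"k_n": 2.5, "f0": 0.15,
                                                       "f_init": 0.15}})
        df = presyn_suppression_curve([-1.0, -0.5, 0.0], cfg, seeds=[1, 2],
                                      duration=6000.0)
        rates = df.sort_values("gamma1", ascending=False)["rate_khz"].to_numpy()
        assert rates[0] > 0.02  # control network-driven firing
        assert rates[-1] < 0.5 * rates[0]  # strong depression suppresses it
        assert np.isfinite(df.attrs["critical_gamma1"])

    def test_grid_outside_range_rejected(self, control_cfg):
        with pytest.raises(InvalidParameterError):
            presyn_suppression_curve([-1.5, 0.0], control_cfg, seeds=[1, 2])
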