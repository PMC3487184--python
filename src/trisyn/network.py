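"""Closed-loop rate feedback: the neuron's output rate feeds its input rate.

The network is collapsed into a single correlation between a neuron's output
rate and its input rate, f_in = f0 + k_N * f_out, realized dynamically as a
first-order relaxation

    df/dt = (k_N * f_out + f0 - f) / tau_N.

The instantaneous f(t) drives an inhomogeneous Poisson event train
(per-step Bernoulli with p = f*dt << 1); f_out is estimated online from a
trailing window (default 1 s, updated every 100 ms) and held between
updates. Depending on (k_N, f0) and the synaptic transfer curve, the loop
settles into a low-activity (spontaneous) state, a high-activity state, or
is bistable between the two.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .config import NetworkConfig, SimulationConfig
from .engine import TrajectoryFrame, _kernel_args, substream
from .errors import InvalidParameterError, NumericalError
from .neuron import mean_rate
from .synapse import exp_relax

__all__ = ["feedback_step", "StimulusWindow", "ClosedLoopResult", "run_closed_loop"]


def feedback_step(f: float, f_out: float, params: NetworkConfig, dt: float) -> float:
    """Exact one-step update of the feedback rate toward k_N*f_out + f0."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    target = params.k_n * f_out + params.f0
    return min(max(exp_relax(f, target, 1.0 / params.tau_n_ms, dt), 0.0), params.f_max)


@dataclass(frozen=True)
class StimulusWindow:
    """Extra Poisson rate (kHz) injected into the input during [t_start, t_stop)."""

    extra_rate: float  # kHz
    t_start: float  # ms
    t_stop: float  # ms

    def __post_init__(self) -> None:
        if not self.t_start < self.t_stop:
            raise InvalidParameterError("stimulus window requires t_start < t_stop")


@dataclass
class ClosedLoopResult:
    """Trajectory and convergence summary of one closed-loop run."""

    t_ms: np.ndarray  # times of the feedback-rate samples (update stride)
    f: np.ndarray  # feedback (input) rate, kHz
    f_out: np.ndarray  # windowed output-rate estimate, kHz
    spikes: np.ndarray  # spike times, ms
    duration: float
    converged_rate: float  # mean output rate over the final tail, kHz
    converged: bool
    seed: int
    trajectory: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t_ms, "f_khz": self.f,
                             "f_out_khz": self.f_out})


def run_closed_loop(cfg: SimulationConfig, f_init: float | None = None,
                    duration: float | None = None, seed: int | None = None,
                    stimulus: StimulusWindow | None = None,
                    record: bool = False, record_stride: int = 100,
                    tail_ms: float = 2000.0) -> ClosedLoopResult:
    """Co-integrate stimulus, synapse, astrocyte, neuron and rate feedback.

    Parameters
    ----------
    f_init : float, optional
        Initial feedback rate (kHz); defaults to ``cfg.network.f_init``. The
        low/high attractor reached in a bistable regime depends on it.
    stimulus : StimulusWindow, optional
        Transient extra input rate, e.g. a short high-frequency spike train
        used to switch a bistable loop from the low to the high state.
    tail_ms : float
        Length of the final window over which the converged rate is averaged.

    Non-convergence is flagged on the result, never raised.
    """
    seed = cfg.seed if seed is None else seed
    duration = cfg.duration_ms if duration is None else duration
    dt = cfg.stimulus.dt_ms
    net = cfg.network
    if duration < 5 * net.window_ms:
        raise InvalidParameterError(
            f"duration ({duration} ms) must cover at least 5 rate windows "
            f"({net.window_ms} ms each)"
        )
    f_init = net.f_init if f_init is None else min(max(f_init, 0.0), net.f_max)
    n_steps = int(round(duration / dt))
    if stimulus is not None and stimulus.extra_rate < 0:
        warnings.warn("negative stimulus extra_rate: total input rate is "
                      "clamped at 0 where the sum goes negative", stacklevel=2)
    if stimulus is not None:
        extra = np.zeros(n_steps)
        i0 = max(int(round(stimulus.t_start / dt)), 0)
        i1 = min(int(round(stimulus.t_stop / dt)), n_steps)
        extra[i0:i1] = stimulus.extra_rate
    else:
        extra = np.zeros(1)
    args = _kernel_args(cfg)
    out = _kernels.simulate_kernel(
        n_steps, dt, substream(seed, "closed-loop"),
        True, np.zeros(1, np.uint8), extra, int(round(cfg.stimulus.tau_ms / dt)),
        args["alpha_x"], args["k0"], args["alpha_i"], args["b0"],
        args["theta_x"], args["k_x"], args["g_syn"],
        args["astro_on"], args["alpha1"], args["alpha2"],
        args["theta1"], args["theta2"], args["kk1"], args["kk2"],
        args["gamma1"], args["gamma2"],
        args["C"], args["g_na"], args["g_k"], args["g_l"],
        args["e_na"], args["e_k"], args["e_l"], args["i_th"],
        args["k_n"], args["f0"], args["tau_n_ms"], f_init, args["f_max"],
        max(int(round(net.window_ms / dt)), 1),
        max(int(round(net.update_ms / dt)), 1),
        args["v_thresh"], args["refr_steps"],
        args["V0"], args["m0"], args["h0"], args["n0"],
        record_stride if record else 0,
    )
    spikes, n_sp, traj, n_rec, f_series, fout_series, n_fser = out
    if n_sp < 0:
        raise NumericalError(f"integration diverged at step {-n_sp} (t={-n_sp * dt:.3f} ms)")
    t_ms = (np.arange(1, n_fser + 1)) * net.update_ms
    converged_rate = mean_rate(spikes, duration, transient=duration - tail_ms)
    converged = _is_converged(fout_series, net)
    return ClosedLoopResult(
        t_ms=t_ms, f=f_series, f_out=fout_series, spikes=spikes,
        duration=duration, converged_rate=converged_rate, converged=converged,
        seed=seed, trajectory=TrajectoryFrame(traj) if record else None,
    )


def _is_converged(fout_series: np.ndarray, net: NetworkConfig,
                  rel_tol: float = 0.05, abs_floor: float = 0.005) -> bool:
    """Relative change of the windowed rate < 5% across the last 3 windows.

    Estimates one window apart (non-overlapping) are compared; sparse-spike
    regimes are handled with an absolute rate floor (kHz) in the denominator.
    """
    per_win = max(int(round(net.window_ms / net.update_ms)), 1)
    idx = [-1 - 2 * per_win, -1 - per_win, -1]
    if len(fout_series) < 1 + 2 * per_win:
        return False
    vals = fout_series[idx]
    ref = max(abs(vals[-1]), abs_floor)
    return bool(np.all(np.abs(np.diff(vals)) <= rel_tol * ref))
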