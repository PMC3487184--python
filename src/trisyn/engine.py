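"""High-level simulation drivers wrapping the jit-compiled kernel.

Seed policy: every run takes one integer seed and deterministically spawns
independent substreams for the event train and for the EPSC amplitudes.
Because the event substream does not depend on the astrocytic condition, two
runs that differ only in (gamma1, gamma2) see the *same* presynaptic event
stream and the same per-pulse uniform draws — condition comparisons are
paired at the level of individual pulses.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .config import SimulationConfig
from .errors import NumericalError
from .neuron import mean_rate, resting_state
from .stimulus import generate_poisson_train, pulses_from_events

__all__ = ["substream", "TrajectoryFrame", "OpenLoopResult", "run_open_loop"]

_TRAJ_COLS = ["time_ms", "V_mV", "X", "I_EPSC", "Y1", "Y2", "I_syn", "f_khz"]


def substream(seed: int, *labels: str) -> int:
    """Deterministic child seed (< 2**31) for a labelled substream."""
    keys = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(l.encode()) for l in labels]
    return int(np.random.SeedSequence(keys).generate_state(1)[0] & 0x7FFFFFFF)


def TrajectoryFrame(traj: np.ndarray) -> pd.DataFrame:
    """Wrap a raw kernel trajectory array into a tidy DataFrame."""
    return pd.DataFrame(traj, columns=_TRAJ_COLS)


@dataclass
class OpenLoopResult:
    """Outcome of one open-loop (no network feedback) run."""

    spikes: np.ndarray  # spike times, ms
    f_in: float  # nominal input rate, kHz
    duration: float  # ms
    transient: float  # ms discarded by f_out
    seed: int
    trajectory: pd.DataFrame | None = None

    @property
    def f_out(self) -> float:
        """Mean post-transient firing rate, kHz."""
        return mean_rate(self.spikes, self.duration, self.transient)


def _kernel_args(cfg: SimulationConfig) -> dict:
    s, a, n, net = cfg.synapse, cfg.astrocyte, cfg.neuron, cfg.network
    rest = resting_state(n)
    return dict(
        alpha_x=s.alpha_x, k0=s.k0, alpha_i=s.alpha_i, b0=s.b0,
        theta_x=s.theta_x, k_x=s.k_x, g_syn=s.g_syn,
        astro_on=a.enabled, alpha1=a.alpha1, alpha2=a.alpha2,
        theta1=a.theta1, theta2=a.theta2, kk1=a.k1, kk2=a.k2,
        gamma1=a.gamma1, gamma2=a.gamma2,
        C=n.C, g_na=n.g_na, g_k=n.g_k, g_l=n.g_l,
        e_na=n.e_na, e_k=n.e_k, e_l=n.e_l, i_th=n.i_th,
        k_n=net.k_n, f0=net.f0, tau_n_ms=net.tau_n_ms,
        f_init=net.f_init, f_max=net.f_max,
        v_thresh=n.v_thresh,
        refr_steps=max(int(round(n.refractory_ms / cfg.stimulus.dt_ms)), 1),
        V0=rest.V, m0=rest.m, h0=rest.h, n0=rest.n,
    )


def run_open_loop(cfg: SimulationConfig, f_in: float, seed: int | None = None,
                  duration: float | None = None, record: bool = False,
                  record_stride: int = 100) -> OpenLoopResult:
    """Simulate the synapse-neuron chain under a Poisson drive at ``f_in`` kHz.

    The network feedback is off: the drive is a homogeneous Poisson train at
    exactly ``f_in`` for the whole run.
    """
    seed = cfg.seed if seed is None else seed
    duration = cfg.duration_ms if duration is None else duration
    dt = cfg.stimulus.dt_ms
    tau = cfg.stimulus.tau_ms
    train = generate_poisson_train(f_in, duration, seed=substream(seed, "events"))
    sig = pulses_from_events(train, tau=tau, dt=dt)
    args = _kernel_args(cfg)
    n_steps = sig.samples.size
    out = _kernels.simulate_kernel(
        n_steps, dt, substream(seed, "amplitudes"),
        False, sig.samples, np.zeros(1), int(round(tau / dt)),
        args["alpha_x"], args["k0"], args["alpha_i"], args["b0"],
        args["theta_x"], args["k_x"], args["g_syn"],
        args["astro_on"], args["alpha1"], args["alpha2"],
        args["theta1"], args["theta2"], args["kk1"], args["kk2"],
        args["gamma1"], args["gamma2"],
        args["C"], args["g_na"], args["g_k"], args["g_l"],
        args["e_na"], args["e_k"], args["e_l"], args["i_th"],
        args["k_n"], args["f0"], args["tau_n_ms"], 0.0, args["f_max"],
        max(int(round(cfg.network.window_ms / dt)), 1),
        max(int(round(cfg.network.update_ms / dt)), 1),
        args["v_thresh"], args["refr_steps"],
        args["V0"], args["m0"], args["h0"], args["n0"],
        record_stride if record else 0,
    )
    spikes, n_sp, traj, n_rec, _, _, _ = out
    if n_sp < 0:
        raise NumericalError(f"integration diverged at step {-n_sp} (t={-n_sp * dt:.3f} ms)")
    return OpenLoopResult(
        spikes=spikes, f_in=f_in, duration=duration, transient=cfg.transient_ms,
        seed=seed, trajectory=TrajectoryFrame(traj) if record else None,
    )
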