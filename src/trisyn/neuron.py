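"""Hodgkin-Huxley spike generation, spike detection and rate estimation.

The membrane follows the classical squid-axon HH equations in the modern
(-65 mV rest) convention,

    C dV/dt = -(I_Na + I_K + I_leak) + I_th + I_syn,

so positive synaptic current depolarizes. Integration is fixed-step RK4 with
the injected current frozen over each step; the linear synaptic subsystems
are advanced separately by exact exponential updates on the same grid.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .config import NeuronConfig
from .errors import InvalidParameterError, NumericalError

__all__ = [
    "HHState",
    "hh_step",
    "steady_gating",
    "resting_state",
    "simulate_hh",
    "detect_spikes",
    "estimate_rate",
    "mean_rate",
]


@dataclass
class HHState:
    """Membrane potential (mV) and gating variables in [0, 1]."""

    V: float = -65.0
    m: float = 0.05
    h: float = 0.6
    n: float = 0.32


def hh_step(state: HHState, I_syn: float, params: NeuronConfig, dt: float) -> HHState:
    """One RK4 step with total depolarizing current ``params.i_th + I_syn``.

    Raises :class:`NumericalError` if the update produces a non-finite state.
    """
    if dt > 0.05:
        raise InvalidParameterError(f"HH integration requires dt <= 0.05 ms, got {dt}")
    V, m, h, n = _kernels.hh_rk4_step(
        state.V, state.m, state.h, state.n, params.i_th + I_syn, dt,
        params.C, params.g_na, params.g_k, params.g_l,
        params.e_na, params.e_k, params.e_l,
    )
    if not np.isfinite(V):
        raise NumericalError(
            f"HH step produced non-finite V from V={state.V}, I={params.i_th + I_syn}"
        )
    return replace(state, V=V, m=m, h=h, n=n)


def steady_gating(V: float) -> tuple[float, float, float]:
    """Steady-state gating (m_inf, h_inf, n_inf) at clamped voltage V."""
    a_m, b_m, a_h, b_h, a_n, b_n = _kernels.hh_rates(V)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def resting_state(params: NeuronConfig | None = None) -> HHState:
    """Resting fixed point (zero synaptic input, I = i_th) of the HH system."""
    p = params or NeuronConfig()

    def dv(V: float) -> float:
        m, h, n = steady_gating(V)
        return _kernels.hh_deriv(V, m, h, n, p.i_th, p.C, p.g_na, p.g_k, p.g_l,
                                 p.e_na, p.e_k, p.e_l)[0]

    V_rest = brentq(dv, -90.0, -50.0, xtol=1e-10)
    m, h, n = steady_gating(V_rest)
    return HHState(V=V_rest, m=m, h=h, n=n)


def simulate_hh(I: float | np.ndarray, duration: float, dt: float = 0.01,
                params: NeuronConfig | None = None,
                state: HHState | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the HH neuron under a constant or per-step current.

    Returns (t, V) sampled at every step. Convenience wrapper used for f-I
    characterization and integrator validation; the full tripartite
    simulation lives in :mod:`trisyn.engine`.
    """
    p = params or NeuronConfig()
    s = state or resting_state(p)
    n_steps = int(round(duration / dt))
    I_arr = np.broadcast_to(np.asarray(I, dtype=float), (n_steps,))
    V = np.empty(n_steps)
    Vc, m, h, n = s.V, s.m, s.h, s.n
    for i in range(n_steps):
        Vc, m, h, n = _kernels.hh_rk4_step(Vc, m, h, n, p.i_th + I_arr[i], dt,
                                           p.C, p.g_na, p.g_k, p.g_l,
                                           p.e_na, p.e_k, p.e_l)
        V[i] = Vc
    if not np.isfinite(V[-1]):
        raise NumericalError("HH integration diverged")
    return np.arange(1, n_steps + 1) * dt, V


def detect_spikes(V: np.ndarray, dt: float, threshold: float = 0.0,
                  refractory: float = 2.0, t0: float = 0.0) -> np.ndarray:
    """Spike times from a sampled voltage trace.

    A spike is an upward crossing of ``threshold`` separated from the
    previous one by at least ``refractory`` ms; the crossing time is linearly
    interpolated between samples.
    """
    if refractory <= 0:
        raise InvalidParameterError("refractory must be > 0")
    V = np.asarray(V, dtype=float)
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    times = []
    last = -np.inf
    for i in up:
        t = t0 + (i + (threshold - V[i]) / (V[i + 1] - V[i])) * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def estimate_rate(spikes: np.ndarray, duration: float, window: float = 1000.0,
                  stride: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window firing rate (kHz) over a spike train.

    Returns (t_end, rate) where each rate is the spike count in the trailing
    ``window`` ms ending at t_end, divided by the window.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    if window > duration:
        raise InvalidParameterError(
            f"window ({window} ms) longer than the trace ({duration} ms)"
        )
    spikes = np.asarray(spikes, dtype=float)
    ends = np.arange(window, duration + 0.5 * stride, stride)
    counts = np.searchsorted(spikes, ends) - np.searchsorted(spikes, ends - window)
    return ends, counts / window


def mean_rate(spikes: np.ndarray, duration: float, transient: float = 0.0) -> float:
    """Post-transient mean firing rate (kHz): count/(duration - transient)."""
    spikes = np.asarray(spikes, dtype=float)
    n = int(np.sum(spikes >= transient))
    return n / (duration - transient)
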