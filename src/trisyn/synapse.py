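"""Mean-field synapse: neurotransmitter X, stochastic EPSCs, dendritic gate.

The presynaptic terminal pool is described by a single mean-field
neurotransmitter amount X(t) relaxing toward ``k_pre`` while the drive pulse
is on and toward 0 otherwise,

    dX/dt = -alpha_x * (X - k_pre * I_pre(t)),

and the mean-field excitatory postsynaptic current relaxes toward a random
per-pulse amplitude A,

    dI_EPSC/dt = -alpha_i * (I_EPSC - A * I_pre(t)).

Amplitudes follow the density P(A) = (2A/b^2) exp(-A^2/b^2) on A >= 0
(a Rayleigh-form law with scale b). The somatic synaptic current is the
EPSC gated by the sigmoidal dendritic integration function S(X),
I_syn = g_syn * I_EPSC * S(X), which filters isolated sub-threshold events.

Both ODEs are linear with piecewise-constant coefficients, so they are
advanced with exact per-step exponential updates (see :func:`exp_relax`);
only the Hodgkin-Huxley subsystem needs RK4.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SynapseState",
    "exp_relax",
    "step_neurotransmitter",
    "release_increment",
    "amplitude_pdf",
    "amplitude_cdf",
    "amplitude_mean",
    "sample_epsc_amplitude",
    "step_epsc",
    "dendritic_gate",
    "synaptic_current",
]


@dataclass
class SynapseState:
    """Instantaneous synapse state."""

    X: float = 0.0  # mean-field neurotransmitter (dimensionless)
    I_epsc: float = 0.0  # mean-field EPSC (dimensionless)
    A_current: float = 0.0  # amplitude attached to the ongoing pulse


def exp_relax(value: float, target: float, rate: float, dt: float) -> float:
    """Exact one-step update of dy/dt = -rate*(y - target) with target frozen.

    This is the exponential-Euler step, exact for piecewise-constant targets:
    y(t+dt) = target + (y - target) * exp(-rate*dt).
    """
    return target + (value - target) * np.exp(-rate * dt)


def step_neurotransmitter(X: float, pulse_on: bool, k_pre: float,
                          alpha_x: float, dt: float) -> float:
    """Advance X by one grid step; relaxes toward k_pre during a pulse, 0 otherwise."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    if k_pre < 0:
        raise InvalidParameterError("k_pre must be >= 0")
    target = k_pre if pulse_on else 0.0
    return max(exp_relax(X, target, alpha_x, dt), 0.0)


def release_increment(X: float, k_pre: float, alpha_x: float) -> float:
    """Per-event contribution dX ~ (k_pre - X)*alpha_x.

    Diagnostic only — the ODE is the source of truth. The increment shrinks
    as X approaches the release efficacy, expressing saturation of the
    mean-field pool.
    """
    return (k_pre - X) * alpha_x


def amplitude_pdf(A: np.ndarray | float, b: float) -> np.ndarray | float:
    """Density P(A) = (2A/b^2) exp(-A^2/b^2) of EPSC amplitudes, A >= 0."""
    A = np.asarray(A, dtype=float)
    out = np.where(A >= 0, (2.0 * A / b**2) * np.exp(-(A**2) / b**2), 0.0)
    return out if out.ndim else float(out)


def amplitude_cdf(A: np.ndarray | float, b: float) -> np.ndarray | float:
    """Closed-form CDF 1 - exp(-A^2/b^2) of the amplitude law."""
    A = np.asarray(A, dtype=float)
    out = np.where(A >= 0, 1.0 - np.exp(-(A**2) / b**2), 0.0)
    return out if out.ndim else float(out)


def amplitude_mean(b: float) -> float:
    """Analytic first moment b*sqrt(pi)/2 of the amplitude law."""
    return b * np.sqrt(np.pi) / 2.0


def sample_epsc_amplitude(b: float, rng: np.random.Generator,
                          size: int | None = None) -> np.ndarray | float:
    """Draw EPSC amplitudes by inverse-CDF: A = b*sqrt(-ln U), U ~ Uniform(0,1)."""
    if b <= 0:
        raise InvalidParameterError(f"amplitude scale b must be > 0, got {b}")
    u = rng.random(size)
    # 1-u in (0, 1], so the log is finite.
    return b * np.sqrt(-np.log1p(-u))


def step_epsc(I_epsc: float, pulse_on: bool, A: float, alpha_i: float, dt: float) -> float:
    """Advance I_EPSC one step; relaxes toward A during a pulse, toward 0 otherwise."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    target = A if pulse_on else 0.0
    return exp_relax(I_epsc, target, alpha_i, dt)


def dendritic_gate(X: np.ndarray | float, theta_x: float, k_x: float) -> np.ndarray | float:
    """Dendritic integration function S(X) = 1/(1+exp(-(X-theta_x)/k_x))."""
    if k_x <= 0:
        raise InvalidParameterError("k_x must be > 0")
    X = np.asarray(X, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp(-(X - theta_x) / k_x))
    return out if out.ndim else float(out)


def synaptic_current(I_epsc: float, S: float, g_syn: float = 1.0) -> float:
    """Somatic synaptic current I_syn = g_syn * I_EPSC * S(X), in uA/cm^2."""
    if not 0.0 <= S <= 1.0:
        raise InvalidParameterError(f"gate S must be in [0, 1], got {S}")
    return g_syn * I_epsc * S
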