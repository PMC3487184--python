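"""Gliotransmitter mean-field dynamics and the two astrocytic modulation channels.

Two gliotransmitter pools are tracked: Y1 (astrocytic glutamate, feeding back
on the presynaptic terminal) and Y2 (D-serine, feeding forward onto the
postsynaptic response). Each obeys the same first-order relaxation,

    dY_k/dt = -alpha_k * (Y_k - H_k(X)),     H_k(X) = 1/(1+exp(-(X-theta_k)/k_k)),

driven by the sigmoidal activation H_k of the synaptic neurotransmitter level
X, so Y_k stays in [0, 1]. Intracellular Ca2+ machinery is deliberately
collapsed into this single activation step.

Modulation is applied continuously:

* presynaptic release efficacy  k_pre = k0 * (1 + gamma1 * Y1)
  (gamma1 < 0 depresses release, gamma1 > 0 potentiates it);
* EPSC amplitude scale          b = b0 * (1 + gamma2 * Y2)
  (gamma2 > 0 upscales postsynaptic responses, e.g. D-serine co-agonism of
  NMDA receptors).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .synapse import exp_relax

__all__ = [
    "GliaState",
    "glia_activation",
    "step_gliotransmitter",
    "presynaptic_scale",
    "postsynaptic_scale",
]


@dataclass
class GliaState:
    """Gliotransmitter concentrations, both dimensionless in [0, 1]."""

    Y1: float = 0.0  # astrocytic glutamate
    Y2: float = 0.0  # D-serine


def glia_activation(X: np.ndarray | float, theta_k: float, k_k: float) -> np.ndarray | float:
    """Equilibrium activation H_k(X) = 1/(1+exp(-(X-theta_k)/k_k))."""
    if k_k <= 0:
        raise InvalidParameterError("k_k must be > 0")
    X = np.asarray(X, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp(-(X - theta_k) / k_k))
    return out if out.ndim else float(out)


def step_gliotransmitter(Y: float, H: float, alpha_k: float, dt: float) -> float:
    """Advance Y_k one step by exact exponential relaxation toward H."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    return min(max(exp_relax(Y, H, alpha_k, dt), 0.0), 1.0)


def presynaptic_scale(k0: float, gamma1: float, Y1: float) -> float:
    """Release efficacy k_pre = k0 * (1 + gamma1 * Y1); must stay >= 0."""
    scale = 1.0 + gamma1 * Y1
    if scale < 0:
        raise InvalidParameterError(
            f"presynaptic scale 1+gamma1*Y1 = {scale:.4g} is negative "
            f"(gamma1={gamma1}, Y1={Y1})"
        )
    return k0 * scale


def postsynaptic_scale(b0: float, gamma2: float, Y2: float) -> float:
    """Live EPSC amplitude scale b = b0 * (1 + gamma2 * Y2)."""
    if b0 <= 0:
        raise InvalidParameterError("b0 must be > 0")
    return b0 * (1.0 + gamma2 * Y2)
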