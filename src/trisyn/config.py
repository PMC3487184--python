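"""Simulation configuration: defaults, validation, presets, (de)serialization.

The default parameter set is the published table for the mean-field
tripartite-synapse model. Time is always in milliseconds, rates in kHz
(events/ms), voltages in mV and currents in uA/cm^2. Several figures in the
source study use parameter values that differ from the defaults; those are
shipped as named presets (see :data:`PRESETS`).
"""
from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidDiscretizationError, InvalidParameterError

__all__ = [
    "StimulusConfig",
    "SynapseConfig",
    "AstrocyteConfig",
    "NeuronConfig",
    "NetworkConfig",
    "SimulationConfig",
    "PRESETS",
    "preset",
    "load_config",
    "config_from_dict",
    "config_hash",
]

#: Calibrated gain mapping the dimensionless product I_EPSC * S(X) onto an HH
#: membrane current (uA/cm^2). Chosen once so that, under the response-curve
#: preset (coincidence-filtering synapse, b0 = 5, no astrocyte), the maximal
#: slope of the control input-output curve sits at f_in ~ 0.2 kHz
#: (see docs/methods.md, "Current-unit calibration").
G_SYN_DEFAULT = 40.0


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class StimulusConfig(_Block):
    """Presynaptic event-train discretization."""

    tau_ms: float = Field(1.0, gt=0, description="pulse width of one release event")
    dt_ms: float = Field(0.01, gt=0, description="integration grid step")

    @model_validator(mode="after")
    def _check_grid(self) -> "StimulusConfig":
        if self.dt_ms >= self.tau_ms:
            raise InvalidDiscretizationError(
                f"stimulus.dt_ms={self.dt_ms} must be smaller than tau_ms={self.tau_ms}"
            )
        if self.dt_ms > 0.05:
            raise InvalidDiscretizationError(
                f"stimulus.dt_ms={self.dt_ms} exceeds 0.05 ms; the HH subsystem "
                "requires dt <= 0.05 ms for stable fixed-step RK4"
            )
        return self


class SynapseConfig(_Block):
    """Mean-field presynaptic neurotransmitter and EPSC parameters."""

    alpha_x: float = Field(0.1, gt=0, description="neurotransmitter clearance rate, 1/ms")
    k0: float = Field(2.0, ge=0, description="baseline release efficacy (k_pre at Y1=0)")
    alpha_i: float = Field(0.1, gt=0, description="EPSC rate constant, 1/ms")
    b0: float = Field(5.0, gt=0, description="baseline EPSC amplitude scale (5-50)")
    theta_x: float = Field(0.2, description="midpoint of the dendritic gate S(X)")
    k_x: float = Field(0.05, gt=0, description="slope of the dendritic gate S(X)")
    g_syn: float = Field(G_SYN_DEFAULT, gt=0, description="I_EPSC*S -> uA/cm^2 gain")


class AstrocyteConfig(_Block):
    """Gliotransmitter dynamics and the two modulation gains.

    gamma1 scales presynaptic release efficacy (negative = depression),
    gamma2 scales the EPSC amplitude distribution (positive = upscaling).
    ``enabled=False`` freezes Y1 = Y2 = 0, i.e. a bipartite synapse.
    """

    enabled: bool = True
    alpha1: float = Field(0.01, gt=0, description="astro glutamate clearance, 1/ms")
    alpha2: float = Field(0.01, gt=0, description="D-serine clearance, 1/ms")
    theta1: float = Field(0.3, description="midpoint of H1(X)")
    theta2: float = Field(0.3, description="midpoint of H2(X)")
    k1: float = Field(0.1, gt=0, description="slope of H1(X)")
    k2: float = Field(0.1, gt=0, description="slope of H2(X)")
    gamma1: float = Field(-0.8, description="presynaptic gain (<0 depression)")
    gamma2: float = Field(0.4, description="postsynaptic gain (>0 upscaling)")

    @model_validator(mode="after")
    def _check_gamma(self) -> "AstrocyteConfig":
        # Y1 is bounded in [0, 1], so release efficacy k0*(1+gamma1*Y1) stays
        # nonnegative iff gamma1 >= -1.
        if 1.0 + min(self.gamma1, 0.0) < 0.0:
            raise InvalidParameterError(
                f"astrocyte.gamma1={self.gamma1}: release efficacy k0*(1+gamma1*Y1) "
                "would go negative for attainable Y1 (requires gamma1 >= -1)"
            )
        if 1.0 + min(self.gamma2, 0.0) < 0.0:
            raise InvalidParameterError(
                f"astrocyte.gamma2={self.gamma2}: amplitude scale b0*(1+gamma2*Y2) "
                "would go negative for attainable Y2 (requires gamma2 >= -1)"
            )
        return self


class NeuronConfig(_Block):
    """Hodgkin-Huxley point neuron (classical squid-axon set, -65 mV rest)."""

    C: float = Field(1.0, gt=0, description="membrane capacitance, uF/cm^2")
    g_na: float = Field(120.0, gt=0, description="max Na conductance, mS/cm^2")
    g_k: float = Field(36.0, gt=0, description="max K conductance, mS/cm^2")
    g_l: float = Field(0.3, gt=0, description="leak conductance, mS/cm^2")
    e_na: float = Field(50.0, description="Na reversal, mV")
    e_k: float = Field(-77.0, description="K reversal, mV")
    e_l: float = Field(-54.4, description="leak reversal, mV")
    i_th: float = Field(0.0, description="constant bias current, uA/cm^2")
    v_thresh: float = Field(0.0, description="spike-detection threshold, mV")
    refractory_ms: float = Field(2.0, gt=0, description="spike-detection dead time")


class NetworkConfig(_Block):
    """Closed-loop rate feedback f_in = f0 + k_N * f_out."""

    k_n: float = Field(3.0, ge=0, description="network feedback gain")
    f0: float = Field(0.025, ge=0, description="spontaneous presynaptic rate, kHz")
    tau_n: float = Field(0.1, gt=0, description="feedback time scale (see tau_is_rate)")
    tau_is_rate: bool = Field(
        True,
        description="if True, tau_n is the rate 1/tau in 1/ms (printed-table "
        "reading, tau = 10 ms); if False, tau_n is the time constant in ms",
    )
    f_init: float = Field(0.025, ge=0, description="initial feedback rate, kHz")
    f_max: float = Field(2.0, gt=0, description="safety cap on instantaneous rate, kHz")
    window_ms: float = Field(1000.0, gt=0, description="trailing f_out window")
    update_ms: float = Field(100.0, gt=0, description="f_out estimate update stride")

    @property
    def tau_n_ms(self) -> float:
        """Feedback time constant in ms under the configured reading."""
        return 1.0 / self.tau_n if self.tau_is_rate else self.tau_n

    @model_validator(mode="after")
    def _check(self) -> "NetworkConfig":
        if self.f_init > self.f_max:
            raise InvalidParameterError(
                f"network.f_init={self.f_init} exceeds f_max={self.f_max}"
            )
        if self.window_ms < self.update_ms:
            raise InvalidParameterError("network.window_ms must be >= update_ms")
        return self


class SimulationConfig(_Block):
    """Fully-resolved simulation configuration (defaults = published table)."""

    schema_version: int = 1
    seed: int = Field(0, ge=0)
    duration_ms: float = Field(10_000.0, gt=0)
    transient_ms: float = Field(1000.0, ge=0, description="discarded at rate estimation")
    stimulus: StimulusConfig = StimulusConfig()
    synapse: SynapseConfig = SynapseConfig()
    astrocyte: AstrocyteConfig = AstrocyteConfig()
    neuron: NeuronConfig = NeuronConfig()
    network: NetworkConfig = NetworkConfig()

    @model_validator(mode="after")
    def _cross_checks(self) -> "SimulationConfig":
        if self.transient_ms >= self.duration_ms:
            raise InvalidParameterError(
                f"transient_ms={self.transient_ms} must be < duration_ms={self.duration_ms}"
            )
        return self

    def with_overrides(self, overrides: dict[str, Any]) -> "SimulationConfig":
        """Return a new config with a nested override dict merged in."""
        base = self.model_dump()
        return SimulationConfig.model_validate(_deep_merge(base, overrides))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


#: Synapse parameter set used by the response-curve and network experiments.
#: With the tabulated defaults a single release event raises X by
#: ~k0*alpha_x*tau = 0.2, which equals the dendritic-gate midpoint theta_x, so
#: isolated events pass the gate and the transfer curve loses its sigmoidal
#: foot. The transmission-figure captions use a slower, weaker synapse
#: (alpha_x = 0.05, k_pre = 1, theta_x = 0.35) for which the gate is a true
#: coincidence filter; the IO-curve and closed-loop experiments inherit it.
FIGURE_SYNAPSE: dict[str, Any] = {
    "alpha_x": 0.05, "k0": 1.0, "theta_x": 0.35, "b0": 5.0,
}

#: Named parameter presets mirroring figure-caption overrides of the defaults.
#: Each entry is a nested override dict applied on top of the table defaults.
PRESETS: dict[str, dict[str, Any]] = {
    "table1_defaults": {},
    # Synaptic-transmission illustration: slower clearance, weaker release.
    "fig1": {"synapse": {**FIGURE_SYNAPSE, "b0": 25.0}},
    # Control input-output curve (no astrocyte), b = 5.
    "fig2": {"synapse": dict(FIGURE_SYNAPSE),
             "astrocyte": {"gamma1": 0.0, "gamma2": 0.0}},
    # Sharp gliotransmitter activation used to illustrate Y_k transients.
    "fig3": {"synapse": dict(FIGURE_SYNAPSE),
             "astrocyte": {"theta1": 0.5, "theta2": 0.5, "k1": 0.01, "k2": 0.01}},
    # Bi-directional modulation of the IO curve.
    "fig5": {"synapse": dict(FIGURE_SYNAPSE),
             "astrocyte": {"gamma1": -0.8, "gamma2": 0.4}},
    # Closed-loop regimes: weak feedback -> spontaneous firing.
    "fig6a": {"synapse": dict(FIGURE_SYNAPSE),
              "astrocyte": {"gamma1": 0.0, "gamma2": 0.0},
              "network": {"k_n": 0.1}},
    # Strong feedback and spontaneous rate beyond the transfer foot ->
    # monostable high-activity state.
    "fig6b": {"synapse": dict(FIGURE_SYNAPSE),
              "astrocyte": {"gamma1": 0.0, "gamma2": 0.0},
              "network": {"k_n": 5.0, "f0": 0.12}},
    # Bistable arrangement (switchable by a transient stimulus).
    "fig6c": {"synapse": dict(FIGURE_SYNAPSE),
              "astrocyte": {"gamma1": 0.0, "gamma2": 0.0},
              "network": {"k_n": 5.0, "f0": 0.05}},
    # Presynaptic-suppression scan (f0 outside the table's 0.02-0.03 range,
    # as in the figure caption).
    "fig7b": {"synapse": dict(FIGURE_SYNAPSE),
              "astrocyte": {"gamma2": 0.0}, "network": {"k_n": 2.5, "f0": 0.09}},
    # k_N bifurcation diagram, control vs bi-directional astrocyte.
    "fig7c": {"synapse": dict(FIGURE_SYNAPSE), "network": {"f0": 0.07}},
    # delta-f0 hysteresis scan, no astrocyte.
    "fig7e": {"synapse": dict(FIGURE_SYNAPSE),
              "astrocyte": {"gamma1": 0.0, "gamma2": 0.0},
              "network": {"k_n": 5.0, "f0": 0.05}},
    # Full-model k_N scan.
    "fig8": {"synapse": dict(FIGURE_SYNAPSE), "network": {"f0": 0.07}},
}


def preset(name: str) -> SimulationConfig:
    """Return the named preset merged onto the table defaults."""
    try:
        overrides = PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; valid: {sorted(PRESETS)}"
        ) from None
    return SimulationConfig().with_overrides(overrides)


def config_from_dict(data: dict[str, Any] | None) -> SimulationConfig:
    """Validate a (possibly partial) config dict against the schema.

    Unknown keys are rejected with the offending key path; omitted keys take
    the table defaults. An optional top-level ``preset`` key applies a named
    preset before the remaining overrides.
    """
    data = dict(data or {})
    name = data.pop("preset", "table1_defaults")
    cfg = preset(name)
    return cfg.with_overrides(data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON config file; an empty file yields the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise InvalidParameterError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def config_hash(cfg: SimulationConfig) -> str:
    """Stable sha256 of the fully-resolved config."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
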