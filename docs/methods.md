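# Methods

`trisyn` simulates a single mean-field "network neuron" whose excitatory
synaptic input is shaped by an astrocyte, and analyses how the astrocytic
modulation reorganizes the neuron's firing regimes once its output rate is
fed back into its input rate. All internal units are milliseconds, kHz
(events/ms), mV and uA/cm².

## Model

**Stimulus.** Presynaptic release events form a Poisson process with rate
f_in. Each event opens a rectangular pulse of width τ = 1 ms in the binary
drive I_pre(t); events closer than τ merge into one longer pulse (the drive
is the indicator of the union of intervals [t_i, t_i+τ)). Event times are
drawn in continuous time (exponential gaps) and snapped to the integration
grid only when the pulse signal is built. In the closed loop, where the rate
f(t) varies, events are generated per step as Bernoulli(f·dt); with
dt = 0.01 ms and f ≤ 2 kHz the per-step probability stays ≤ 0.02.

**Synapse.** The mean-field neurotransmitter amount X relaxes toward the
release efficacy k_pre while the drive is on and clears otherwise:

    dX/dt = -α_x (X - k_pre · I_pre(t))

The mean-field EPSC relaxes toward a per-pulse random amplitude A:

    dI_EPSC/dt = -α_i (I_EPSC - A · I_pre(t))

with A drawn at each pulse onset from the Rayleigh-form law
P(A) = (2A/b²) exp(-A²/b²) by inverse CDF, A = b√(-ln U). The somatic
current is the EPSC gated by the sigmoidal dendritic integration function,

    I_syn = g_syn · I_EPSC · S(X),    S(X) = 1/(1+exp(-(X-θ_x)/k_x)),

which filters sub-threshold (isolated) events: only when enough events
summate temporally does X cross θ_x and the gate open.

**Astrocyte.** Two gliotransmitter pools — Y₁ (astrocytic glutamate) and Y₂
(D-serine) — integrate the synaptic activity through a sigmoidal activation
of X and relax with slow clearance (α_k = 0.01/ms, i.e. 100 ms):

    dY_k/dt = -α_k (Y_k - H_k(X)),    H_k(X) = 1/(1+exp(-(X-θ_k)/k_k)).

Intracellular Ca²⁺/IP₃ machinery is deliberately collapsed into this single
activation step. Modulation is applied continuously:
k_pre = k₀(1+γ₁Y₁) (γ₁ < 0: presynaptic depression) and
b = b₀(1+γ₂Y₂) (γ₂ > 0: postsynaptic EPSC upscaling, the D-serine/NMDA
effect). Both Y_k stay in [0, 1] because their drive does.

**Neuron.** Classical squid-axon Hodgkin–Huxley equations in the −65 mV rest
convention, C dV/dt = −(I_Na+I_K+I_L) + I_th + I_syn, with the sign chosen so
synaptic input depolarizes. I_th defaults to 0: the neuron is input-driven.
Spikes are upward 0-mV crossings separated by ≥ 2 ms; a run's scalar f_out is
the post-transient mean rate, and time-resolved rates use a trailing 1-s
window.

**Network feedback.** The network is collapsed into a correlation between
the neuron's output and input rates, f_in = f₀ + k_N·f_out, realized
dynamically as df/dt = (k_N·f_out + f₀ − f)/τ_N. f_out is estimated online
from a trailing 1-s window updated every 100 ms and held between updates.
The estimator ring is warm-started at the rate self-consistent with the
initial condition, (f_init − f₀)/k_N, so a high initialization is not
spuriously collapsed while the first window fills.

## Numerics

- The linear subsystems (X, I_EPSC, Y₁, Y₂, f) are advanced with exact
  per-step exponential updates (targets frozen over one step); these compose
  exactly over constant-drive segments, which the tests verify to < 1e-6
  relative error.
- The HH membrane uses fixed-step RK4 at dt = 0.01 ms with I_syn frozen over
  the step; the spike upstroke (~1 ms) is then resolved by ~100 steps.
  Validated against an adaptive high-accuracy integration of the same vector
  field (< 0.1 mV RMS subthreshold; spike times shift < 0.05 ms when dt is
  halved).
- Gating variables are clamped to [0, 1] against round-off; X is clamped
  below at 0. A non-finite state aborts the run with an error naming the
  step.
- Spike times are linearly interpolated within the crossing step.
- Inner loops are jit-compiled (numba); one 10-s simulation takes ~0.3 s.

## Randomness and pairing

One integer seed deterministically spawns independent substreams for the
event train and for the EPSC amplitudes. The event substream does not depend
on the astrocytic condition, and exactly one amplitude is drawn per pulse
onset, so two runs differing only in (γ₁, γ₂) see identical event streams
and identical per-pulse uniforms: condition comparisons are paired at the
level of individual pulses. With γ₁ = γ₂ = 0 a tripartite run is
bit-identical to a run with the astrocyte disabled.

## Parameters

The package defaults are the published table values: α_x = 0.1/ms, k₀ = 2,
α_i = 0.1/ms, b₀ = 5 (range 5–50), θ_x = 0.2, k_x = 0.05, α₁ = α₂ = 0.01/ms,
θ₁,₂ = 0.3, k₁,₂ = 0.1, γ₁ = −0.8, γ₂ = 0.4, f₀ = 0.025 kHz (mid of the
stated 0.02–0.03 range), k_N = 3. The feedback time scale is printed as the
rate 0.1 ms⁻¹; the default reads it as 1/τ_N (τ_N = 10 ms) with a
`tau_is_rate` switch exposing the literal-time reading.

**Figure-series synapse.** With the tabulated synapse a single release event
raises X by ≈ k₀·α_x·τ = 0.2, exactly the gate midpoint θ_x, so isolated
events pass the dendritic gate, the transfer curve has no foot, and no
calibration of g_syn produces either a maximal slope near f_in = 0.2 kHz or
closed-loop bistability (we verified both by direct scans). The
transmission-figure captions use a slower, weaker synapse — α_x = 0.05/ms,
k_pre = 1, θ_x = 0.35 — for which the gate is a genuine coincidence filter
(per-event increment 0.05 « θ_x). All response-curve and network presets
(`fig2` … `fig8`) therefore carry this synapse set; the package default
remains the table.

**Current-unit calibration.** The gain g_syn mapping the dimensionless
I_EPSC·S onto an HH current is not specified by the model's source; it was
calibrated once, on the control response-curve preset (figure-series
synapse, b₀ = 5, no astrocyte), so that the maximal slope of f_out(f_in)
falls at f_in ≈ 0.2 kHz. This gives g_syn = 40 uA/cm², frozen as the package
default. Beyond f_in ≈ 0.55 kHz this drive reaches HH depolarization block
and the control curve bends down; response-curve grids therefore top out at
0.5 kHz, and the wider comparison grid (to 0.65–0.75 kHz) is used only where
the modulated condition is probed.

## What the experiments compute

- **IO curve** (`scan_io_curve`): open-loop Monte-Carlo estimate of
  f_out = Q(f_in); default budget 10 s per run with a 1-s discard, ≥ 5 seeds
  per grid point. Summarized by a least-squares logistic
  Q(f) = floor + L/(1+exp(−(f−x₀)/s)); with the defaults L ≈ 0.078 kHz,
  x₀ ≈ 0.24 kHz, s ≈ 0.05 kHz, residual RMS ≈ 2% of L.
- **Condition comparison** (`compare_conditions`): pointwise paired t-tests
  on shared seeds; with γ₁ = −0.8, γ₂ = 0.4 the Δf_out profile is the
  high-pass signature: no change at the lowest rates, depression through the
  mid band, potentiation at the top of the curve.
- **Steady states** (`steady_states`): all roots of f = f₀ + k_N·Q(f) by
  dense-grid bracketing plus bisection (|g| < 1e-9); a fixed point is stable
  iff k_N·Q′(f*) < 1 — the standard cobweb slope condition for the composed
  one-dimensional rate map, adopted here as the formal version of the
  "independent relaxation" stability argument. For a logistic Q the root
  count is 1, 2 (fold) or 3, and with 3 the middle root is always unstable.
- **Bifurcation scan** (`bifurcation_scan`): closed-loop runs from a low and
  a high initial rate per grid value and seed; a point is bistable when the
  two converged rates differ by > 20% of the scan's dynamic range (our
  threshold; ≥ 2 seeds per point). At f₀ = 0.07 kHz the control loop is
  bistable over k_N ≈ 6–26 and the bi-directional astrocyte condition over
  k_N ≈ 6–32: the depressed transfer foot lets the low state survive to
  larger gains, broadening the bistable interval, while the fold to the high
  state moves to slightly larger k_N.
- **Hysteresis scan** (`hysteresis_scan`): warm-started up/down sweeps of a
  parameter (each run initialized at the previous attractor's input rate);
  thresholds are the largest rate jumps, reported only when they exceed 40%
  of the sweep's dynamic range. Sweeping δf₀ at k_N = 5, f₀ = 0.05 gives an
  up-transition near δf₀ ≈ +0.06 and a down-transition near δf₀ ≈ −0.04 —
  the two saddle-node folds of the rate map.
- **Presynaptic suppression** (`presyn_suppression_curve`): closed-loop rate
  vs γ₁ ∈ [−1, 0]; the critical gain is the largest drop between adjacent
  grid points.

## What the synthetic conditions do and do not show

All inputs are generated internally; there is no recorded data anywhere in
the pipeline. The Poisson drive, Rayleigh-form amplitudes and mean-field
scalings are the model's own assumptions, so passing tests demonstrate
internal consistency of the implementation and the regime structure of the
model — not that a biological synapse behaves this way. In particular the
model omits short-term plasticity, receptor kinetics, Ca²⁺/IP₃ dynamics,
astrocyte–astrocyte coupling, synchronizing slow inward currents, feedback
delays, and any explicit network topology (the single correlation k_N stands
in for all of it).

## Known limitations

- The converged-rate estimate of sparse low states rests on few spikes; the
  convergence flag uses a 5% relative criterion with a 0.005 kHz floor and is
  informational only.
- Near bistable-interval endpoints the attractor reached is noise-dependent;
  interval endpoints from `bifurcation_scan` are grid-resolution quantities.
- The logistic summary of Q ignores the depolarization-block bend above
  ~0.55 kHz (control); steady-state analysis is only trusted where the fit
  covers the rates the loop visits.
- Monte-Carlo budgets (run lengths, seed counts, grids) are package choices;
  they are stated next to each experiment and scale linearly in cost.
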