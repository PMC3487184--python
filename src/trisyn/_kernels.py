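"""Jit-compiled inner loops for the full tripartite-synapse simulation.

One kernel integrates the whole coupled system on a fixed grid of step dt:

* binary pulse drive (precomputed for open-loop runs, Bernoulli-generated
  per step from the instantaneous feedback rate for closed-loop runs);
* linear subsystems X, I_EPSC, Y1, Y2 via exact exponential-Euler updates
  (targets frozen over one step);
* Hodgkin-Huxley membrane via classical RK4 with the synaptic current held
  constant over the step;
* online spike detection (upward threshold crossing + refractory) and, in
  closed-loop mode, a trailing-window output-rate estimator driving the
  first-order feedback rate f(t).

Per-step update order: pulse state -> (on pulse onset) amplitude draw with
the live scale b0*(1+gamma2*Y2) -> X update with the live efficacy
k0*(1+gamma1*Y1) -> Y updates toward H_k of the freshly updated X ->
I_EPSC update -> I_syn = g_syn*I_EPSC*S(X) -> HH RK4 step -> spike test ->
feedback-rate update. With the astrocyte disabled the Y updates are skipped
(Y stays 0) but the random-number stream is untouched, so a run with
gamma1 = gamma2 = 0 is bit-identical to a bipartite run at the same seed.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hh_rates", "hh_deriv", "hh_rk4_step", "simulate_kernel"]


@njit(cache=True)
def hh_rates(V):
    """Classical squid-axon gating rates (1/ms) in the -65 mV rest convention."""
    dv = V + 40.0
    if abs(dv) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * dv / (1.0 - np.exp(-dv / 10.0))
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    dv = V + 55.0
    if abs(dv) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * dv / (1.0 - np.exp(-dv / 10.0))
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True)
def hh_deriv(V, m, h, n, I_inj, C, g_na, g_k, g_l, e_na, e_k, e_l):
    """Time derivatives of (V, m, h, n); I_inj > 0 depolarizes."""
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(V)
    i_na = g_na * m * m * m * h * (V - e_na)
    i_k = g_k * n * n * n * n * (V - e_k)
    i_l = g_l * (V - e_l)
    dV = (-(i_na + i_k + i_l) + I_inj) / C
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dn = a_n * (1.0 - n) - b_n * n
    return dV, dm, dh, dn


@njit(cache=True)
def hh_rk4_step(V, m, h, n, I_inj, dt, C, g_na, g_k, g_l, e_na, e_k, e_l):
    """One fixed-step RK4 update with the injected current frozen over dt."""
    k1V, k1m, k1h, k1n = hh_deriv(V, m, h, n, I_inj, C, g_na, g_k, g_l, e_na, e_k, e_l)
    k2V, k2m, k2h, k2n = hh_deriv(V + 0.5 * dt * k1V, m + 0.5 * dt * k1m,
                                  h + 0.5 * dt * k1h, n + 0.5 * dt * k1n,
                                  I_inj, C, g_na, g_k, g_l, e_na, e_k, e_l)
    k3V, k3m, k3h, k3n = hh_deriv(V + 0.5 * dt * k2V, m + 0.5 * dt * k2m,
                                  h + 0.5 * dt * k2h, n + 0.5 * dt * k2n,
                                  I_inj, C, g_na, g_k, g_l, e_na, e_k, e_l)
    k4V, k4m, k4h, k4n = hh_deriv(V + dt * k3V, m + dt * k3m,
                                  h + dt * k3h, n + dt * k3n,
                                  I_inj, C, g_na, g_k, g_l, e_na, e_k, e_l)
    V = V + dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
    m = m + dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
    h = h + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
    n = n + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
    # Clamp gating against round-off excursions.
    m = min(max(m, 0.0), 1.0)
    h = min(max(h, 0.0), 1.0)
    n = min(max(n, 0.0), 1.0)
    return V, m, h, n


@njit(cache=True)
def simulate_kernel(
    n_steps, dt, amp_seed,
    closed_loop, pulse, extra_rate, tau_steps,
    # synapse
    alpha_x, k0, alpha_i, b0, theta_x, k_x, g_syn,
    # astrocyte
    astro_on, alpha1, alpha2, theta1, theta2, kk1, kk2, gamma1, gamma2,
    # neuron
    C, g_na, g_k, g_l, e_na, e_k, e_l, i_th,
    # network feedback (closed loop only)
    k_n, f0, tau_n_ms, f_init, f_max, win_steps, upd_steps,
    # spike detection
    v_thresh, refr_steps,
    # initial HH state
    V0, m0, h0, n0,
    # recording stride (0 = no trajectory)
    record_stride,
):
    """Integrate the full system for ``n_steps`` grid steps.

    Open loop (``closed_loop=False``): the uint8 array ``pulse`` (length
    n_steps) is the drive; the feedback state f is not used.
    Closed loop: events are generated per step as Bernoulli(f(t)*dt), each
    opening/extending a pulse of ``tau_steps`` steps; ``extra_rate`` (length
    n_steps, kHz) is added to the instantaneous rate (stimulus injection).

    Returns (spike_times, n_spikes, trajectory, n_rec, f_series, fout_series,
    n_fser). Trajectory columns: t, V, X, I_epsc, Y1, Y2, I_syn, f.
    """
    np.random.seed(amp_seed)
    ex = np.exp(-alpha_x * dt)
    ei = np.exp(-alpha_i * dt)
    e1 = np.exp(-alpha1 * dt)
    e2 = np.exp(-alpha2 * dt)
    ef = np.exp(-dt / tau_n_ms)

    X = 0.0
    I_epsc = 0.0
    Y1 = 0.0
    Y2 = 0.0
    A = 0.0
    V = V0
    m = m0
    h = h0
    n = n0
    f = f_init

    max_spikes = int(n_steps * dt / (refr_steps * dt)) + 4
    spikes = np.empty(max_spikes, np.float64)
    n_sp = 0
    last_spike_step = -refr_steps - 1

    # Output-rate estimator: ring buffer of spike counts per update bin.
    # Warm-started at the rate self-consistent with f_init (the estimate a
    # loop already sitting at f_init would produce), so the feedback does not
    # spuriously collapse during the first, still-empty window.
    n_bins = max(win_steps // upd_steps, 1)
    fout_init = (f_init - f0) / k_n if (closed_loop and k_n > 0.0) else 0.0
    if fout_init < 0.0:
        fout_init = 0.0
    bin_counts = np.full(n_bins, fout_init * upd_steps * dt)
    cur_count = 0.0
    ring = 0
    fout_est = fout_init
    n_fser = n_steps // upd_steps + 1
    f_series = np.zeros(n_fser, np.float64)
    fout_series = np.zeros(n_fser, np.float64)
    fser_i = 0

    if record_stride > 0:
        n_rec_cap = n_steps // record_stride + 1
    else:
        n_rec_cap = 1
    traj = np.zeros((n_rec_cap, 8), np.float64)
    n_rec = 0

    pulse_until = -1
    pulse_prev = False
    has_extra = extra_rate.shape[0] == n_steps

    for i in range(n_steps):
        # --- stimulus ---------------------------------------------------
        if closed_loop:
            rate = f
            if has_extra:
                rate += extra_rate[i]
            if rate < 0.0:
                rate = 0.0
            elif rate > f_max:
                rate = f_max
            if np.random.random() < rate * dt:
                pulse_until = i + tau_steps
            pulse_on = i < pulse_until
        else:
            pulse_on = pulse[i] == 1

        if pulse_on and not pulse_prev:
            # Fresh amplitude for this (possibly merged) pulse, with the
            # live D-serine-upscaled amplitude scale.
            b_live = b0 * (1.0 + gamma2 * Y2) if astro_on else b0
            u = np.random.random()
            A = b_live * np.sqrt(-np.log(1.0 - u))
        pulse_prev = pulse_on

        # --- linear subsystems (exact exponential updates) ---------------
        k_pre = k0 * (1.0 + gamma1 * Y1) if astro_on else k0
        x_target = k_pre if pulse_on else 0.0
        X = x_target + (X - x_target) * ex
        if X < 0.0:
            X = 0.0

        if astro_on:
            H1 = 1.0 / (1.0 + np.exp(-(X - theta1) / kk1))
            H2 = 1.0 / (1.0 + np.exp(-(X - theta2) / kk2))
            Y1 = H1 + (Y1 - H1) * e1
            Y2 = H2 + (Y2 - H2) * e2

        i_target = A if pulse_on else 0.0
        I_epsc = i_target + (I_epsc - i_target) * ei

        S = 1.0 / (1.0 + np.exp(-(X - theta_x) / k_x))
        I_syn = g_syn * I_epsc * S

        # --- membrane ----------------------------------------------------
        V_prev = V
        V, m, h, n = hh_rk4_step(V, m, h, n, i_th + I_syn, dt,
                                 C, g_na, g_k, g_l, e_na, e_k, e_l)
        if not np.isfinite(V):
            # Signal blow-up through the spike count; wrapper raises.
            return spikes[:0], -(i + 1), traj[:0], 0, f_series[:0], fout_series[:0], 0

        spiked = False
        if V_prev < v_thresh <= V and i - last_spike_step >= refr_steps:
            # Linear interpolation of the crossing time inside the step.
            frac = (v_thresh - V_prev) / (V - V_prev)
            if n_sp < max_spikes:
                spikes[n_sp] = (i + frac) * dt
                n_sp += 1
            last_spike_step = i
            spiked = True

        # --- network feedback --------------------------------------------
        if closed_loop:
            if spiked:
                cur_count += 1
            if (i + 1) % upd_steps == 0:
                bin_counts[ring] = cur_count
                cur_count = 0.0
                ring = (ring + 1) % n_bins
                total = 0.0
                for bidx in range(n_bins):
                    total += bin_counts[bidx]
                fout_est = total / (n_bins * upd_steps * dt)
                if fser_i < n_fser:
                    f_series[fser_i] = f
                    fout_series[fser_i] = fout_est
                    fser_i += 1
            target = k_n * fout_est + f0
            f = target + (f - target) * ef
            if f < 0.0:
                f = 0.0
            elif f > f_max:
                f = f_max

        # --- recording -----------------------------------------------------
        if record_stride > 0 and i % record_stride == 0:
            traj[n_rec, 0] = (i + 1) * dt
            traj[n_rec, 1] = V
            traj[n_rec, 2] = X
            traj[n_rec, 3] = I_epsc
            traj[n_rec, 4] = Y1
            traj[n_rec, 5] = Y2
            traj[n_rec, 6] = I_syn
            traj[n_rec, 7] = f
            n_rec += 1

    return spikes[:n_sp], n_sp, traj[:n_rec], n_rec, f_series[:fser_i], fout_series[:fser_i], fser_i
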