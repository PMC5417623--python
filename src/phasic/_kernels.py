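"""Numba-jitted inner loops.

Everything here is deliberately free of Python objects: the public modules
unpack their dataclasses into scalars/arrays before calling in.  All kernels
are deterministic given the ``numpy.random.Generator`` they receive.
"""

import numpy as np
from numba import njit

# epsilon-mode codes
EPS_CONST = 0
EPS_VOLTAGE = 1

# barrier-model variant codes
VARIANT_CLASSIC = 0
VARIANT_RIGHT_MOVING = 1
VARIANT_PHASIC = 2

# sinusoid clock codes for the thinning simulator
CLOCK_ABSOLUTE = 0
CLOCK_PER_RESET = 1
CLOCK_ENDOGENOUS = 2


@njit(cache=True)
def eps_of_v_scalar(v, eps_lo, eps_hi, v_half, v_slope):
    # logistic blend between the hyperpolarized (eps_hi) and depolarized
    # (eps_lo) plateaus; written in the overflow-safe two-branch form
    x = (v - v_half) / v_slope
    if x > 0.0:
        e = np.exp(-x)
        return (eps_lo + eps_hi * e) / (1.0 + e)
    e = np.exp(x)
    return (eps_hi + eps_lo * e) / (1.0 + e)


@njit(cache=True)
def em_cell(rng, v0, w0, n_steps, dt, tau_v, D, A, phi,
            eps_mode, eps_const, eps_lo, eps_hi, v_half, v_slope,
            w_c, spike_out, record, v_out, w_out, xi_out):
    """Euler-Maruyama path of one cell with online upward w_c detection.

    Returns (n_spikes, status); status is -1 on success, else the step index
    at which the state became non-finite.  When ``record`` is nonzero the
    full (v, w) path is stored, and the unit noise deviates eta_n are stored
    in ``xi_out`` scaled by 1/sqrt(dt) as an estimate of xi(t).
    """
    v = v0
    w = w0
    amp = np.sqrt(2.0 * D * dt) / tau_v
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    two_pi_phi = 2.0 * np.pi * phi
    n_spk = 0
    if record != 0:
        v_out[0] = v
        w_out[0] = w
    for n in range(n_steps):
        if eps_mode == EPS_VOLTAGE:
            eps = eps_of_v_scalar(v, eps_lo, eps_hi, v_half, v_slope)
        else:
            eps = eps_const
        signal = A * np.sin(two_pi_phi * (n * dt)) if A != 0.0 else 0.0
        eta = rng.standard_normal() if D > 0.0 else 0.0
        v_new = v + dt * ((v * (0.1 - v) * (v - 1.0) - w + signal) / tau_v) \
            + amp * eta
        w_new = w + dt * eps * v
        if not (np.isfinite(v_new) and np.isfinite(w_new)):
            return n_spk, n
        if w < w_c and w_new >= w_c:
            if n_spk < spike_out.shape[0]:
                spike_out[n_spk] = n * dt + dt * (w_c - w) / (w_new - w)
            n_spk += 1
        v = v_new
        w = w_new
        if record != 0:
            v_out[n + 1] = v
            w_out[n + 1] = w
            if xi_out.shape[0] > 0:
                xi_out[n] = eta * inv_sqrt_dt
    return n_spk, -1


@njit(cache=True)
def rk4_batch(v0s, w0s, n_steps, dt, tau_v, A, phi,
              eps_mode, eps_const, eps_lo, eps_hi, v_half, v_slope,
              w_c, spike_counts, record, v_out, w_out):
    """Fixed-step RK4 for the deterministic system, batched over ICs.

    ``spike_counts[i]`` receives the number of upward w_c crossings of cell i.
    Returns -1 on success or the first step index with a non-finite state.
    """
    two_pi_phi = 2.0 * np.pi * phi
    n_ic = v0s.shape[0]
    for i in range(n_ic):
        v = v0s[i]
        w = w0s[i]
        if record != 0:
            v_out[i, 0] = v
            w_out[i, 0] = w
        n_spk = 0
        for n in range(n_steps):
            t = n * dt
            # classic RK4 on (v, w)
            k1v, k1w = _fn_drift(v, w, t, tau_v, A, phi, two_pi_phi,
                                 eps_mode, eps_const, eps_lo, eps_hi,
                                 v_half, v_slope)
            k2v, k2w = _fn_drift(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w,
                                 t + 0.5 * dt, tau_v, A, phi, two_pi_phi,
                                 eps_mode, eps_const, eps_lo, eps_hi,
                                 v_half, v_slope)
            k3v, k3w = _fn_drift(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w,
                                 t + 0.5 * dt, tau_v, A, phi, two_pi_phi,
                                 eps_mode, eps_const, eps_lo, eps_hi,
                                 v_half, v_slope)
            k4v, k4w = _fn_drift(v + dt * k3v, w + dt * k3w,
                                 t + dt, tau_v, A, phi, two_pi_phi,
                                 eps_mode, eps_const, eps_lo, eps_hi,
                                 v_half, v_slope)
            v_new = v + dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
            w_new = w + dt * (k1w + 2.0 * k2w + 2.0 * k3w + k4w) / 6.0
            if not (np.isfinite(v_new) and np.isfinite(w_new)):
                return n
            if w < w_c and w_new >= w_c:
                n_spk += 1
            v = v_new
            w = w_new
            if record != 0:
                v_out[i, n + 1] = v
                w_out[i, n + 1] = w
        spike_counts[i] = n_spk
    return -1


@njit(cache=True, inline="always")
def _fn_drift(v, w, t, tau_v, A, phi, two_pi_phi,
              eps_mode, eps_const, eps_lo, eps_hi, v_half, v_slope):
    if eps_mode == EPS_VOLTAGE:
        eps = eps_of_v_scalar(v, eps_lo, eps_hi, v_half, v_slope)
    else:
        eps = eps_const
    signal = A * np.sin(two_pi_phi * t) if A != 0.0 else 0.0
    dv = (v * (0.1 - v) * (v - 1.0) - w + signal) / tau_v
    dw = eps * v
    return dv, dw


@njit(cache=True)
def hazard_scalar(dU, D, gamma, beta, p_exp):
    return gamma * np.exp(-beta * dU ** p_exp / D)


@njit(cache=True)
def moving_barrier_scalar(t, v_R, mb_amp, mb_freq, mb_shift1, mb_decay,
                          mb_shift2):
    return v_R - mb_amp * np.sin(mb_freq * (t + mb_shift1)) \
        * np.exp(-mb_decay * (t + mb_shift2))


@njit(cache=True)
def thinning_segment(rng, state, t_seg_end, gamma, beta, p_exp, D, A, phi,
                     dU_L, v_R, mb_amp, mb_freq, mb_shift1, mb_decay,
                     mb_shift2, variant, clock, spike_out, left_out):
    """Thinning simulation of the two-barrier point process over one segment.

    ``state`` = [t, tau, psi0, t_last_spike] is updated in place; ``tau`` is
    the time since the last barrier-clock reset.  Candidate events arrive at
    rate 2*gamma (a hard bound, since each hazard is bounded by gamma) and
    are accepted as left/right crossings by rejection.

    Returns (n_spikes, n_lefts, status): status 0 ok, 1 barrier collapsed
    (negative height: signal amplitude too large), 2 a buffer filled (caller
    must drain and continue).
    """
    bound = 2.0 * gamma
    period = 1.0 / phi if phi > 0.0 else 0.0
    two_pi_phi = 2.0 * np.pi * phi
    t = state[0]
    tau = state[1]
    psi0 = state[2]
    t_last_spike = state[3]
    n_sp = 0
    n_lf = 0
    status = 0
    while True:
        dt_c = rng.exponential(1.0 / bound)
        if t + dt_c > t_seg_end:
            tau += t_seg_end - t
            t = t_seg_end
            break
        t += dt_c
        tau += dt_c
        if A != 0.0:
            if clock == CLOCK_ABSOLUTE:
                s = A * np.sin(two_pi_phi * t)
            else:
                # per-reset and endogenous clocks reference the sinusoid to
                # the most recent barrier reset with offset psi0
                s = A * np.sin(two_pi_phi * (tau + psi0))
        else:
            s = 0.0
        if variant == VARIANT_CLASSIC:
            bR = v_R - s
        else:
            bR = moving_barrier_scalar(tau, v_R, mb_amp, mb_freq, mb_shift1,
                                       mb_decay, mb_shift2) - s
        if bR < 0.0:
            status = 1
            break
        hR = hazard_scalar(bR, D, gamma, beta, p_exp)
        if variant == VARIANT_PHASIC:
            bL = dU_L - s
            if bL < 0.0:
                status = 1
                break
            hL = hazard_scalar(bL, D, gamma, beta, p_exp)
        else:
            hL = 0.0
        u = rng.random() * bound
        if u < hL:
            # left crossing: barrier clock resets, sinusoid offset psi0 kept
            # (the per-reset clock mirrors the renewal theory's convention)
            if n_lf >= left_out.shape[0]:
                status = 2
                break
            left_out[n_lf] = t
            n_lf += 1
            tau = 0.0
        elif u < hL + hR:
            if n_sp >= spike_out.shape[0]:
                status = 2
                break
            spike_out[n_sp] = t
            n_sp += 1
            if clock == CLOCK_PER_RESET and period > 0.0:
                # exogenous bookkeeping: the next ISI starts at the phase
                # reached at this spike (endogenous keeps psi0 fixed)
                psi0 = (psi0 + (t - t_last_spike)) % period
            t_last_spike = t
            tau = 0.0
    state[0] = t
    state[1] = tau
    state[2] = psi0
    state[3] = t_last_spike
    return n_sp, n_lf, status
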