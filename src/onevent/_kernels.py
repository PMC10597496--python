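"""Numba-compiled fixed-step integration kernels.

All kernels operate on batches of independent model instances that share a
membrane/synapse parameterization and a synaptic event schedule, which is how
the determinism experiments evaluate many initializations of one stimulus
window in a single pass.

Unit conventions (matching common simulator practice):
    membrane conductances  S/cm^2          reversal potentials  mV
    capacitance            uF/cm^2         membrane area        cm^2
    synaptic conductance   uS              time                 ms
Membrane current density is 1000*g*(V-E) in uA/cm^2; a synaptic event of
weight w uS contributes a point current w*(V-e_rev) nA spread over the
compartment area.
"""

import numpy as np
from numba import njit

HH = 0
WB = 1

# parameter-vector layout used by the kernels
# mp: [gNa, gK, gL, ENa, EK, EL, Cm, area]
# sp: [w_exc, w_inh, tau_exc, tau_inh, e_exc, e_inh]


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity at x = 0 -> y
    u = x / y
    if abs(u) < 1e-6:
        return y + 0.5 * x
    return x / (1.0 - np.exp(-u))


@njit(cache=True, inline="always")
def _hh_rates(v):
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, inline="always")
def _wb_rates(v):
    # phi = 5 speeds h and n; m is instantaneous and unscaled
    am = 0.1 * _vtrap(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 5.0 * 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-0.1 * (v + 28.0)))
    an = 5.0 * 0.01 * _vtrap(v + 34.0, 10.0)
    bn = 5.0 * 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def integrate_kernel(kind, mp, sp, V, m, h, n, ge, gi,
                     ev_step, ev_exc, n_steps, dt,
                     vm_out, gates_out, syn_out, record_aux):
    """Advance a batch of instances over ``n_steps`` fixed steps of ``dt``.

    ``V, m, h, n, ge, gi`` are (B,) state arrays updated in place; sample k
    of ``vm_out`` (B, n_steps+1) holds the state after events scheduled at
    grid index k have been applied.  Gating variables advance by the
    exponential (Rush-Larsen) update; the voltage by a trapezoid-consistent
    semi-implicit update with conductances frozen over the step.  Synaptic
    events add their weight at their grid index and the two exponential
    conductances decay analytically between samples.
    """
    B = V.shape[0]
    gna, gk, gl = mp[0] * 1000.0, mp[1] * 1000.0, mp[2] * 1000.0  # -> mS/cm^2
    ena, ek, el, cm, area = mp[3], mp[4], mp[5], mp[6], mp[7]
    w_e, w_i, tau_e, tau_i, e_e, e_i = sp[0], sp[1], sp[2], sp[3], sp[4], sp[5]
    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    syn_scale = 1e-3 / area  # uS*mV (nA) -> uA/cm^2
    n_ev = ev_step.shape[0]
    iev = 0
    for k in range(n_steps + 1):
        while iev < n_ev and ev_step[iev] == k:
            if ev_exc[iev] != 0:
                for b in range(B):
                    ge[b] += w_e
            else:
                for b in range(B):
                    gi[b] += w_i
            iev += 1
        for b in range(B):
            vm_out[b, k] = V[b]
        if record_aux:
            for b in range(B):
                gates_out[b, k, 0] = m[b]
                gates_out[b, k, 1] = h[b]
                gates_out[b, k, 2] = n[b]
                syn_out[b, k, 0] = ge[b]
                syn_out[b, k, 1] = gi[b]
        if k == n_steps:
            break
        for b in range(B):
            v = V[b]
            if kind == HH:
                am, bm, ah, bh, an, bn = _hh_rates(v)
                minf = am / (am + bm)
                m[b] = minf + (m[b] - minf) * np.exp(-dt * (am + bm))
            else:
                am, bm, ah, bh, an, bn = _wb_rates(v)
                m[b] = am / (am + bm)
            hinf = ah / (ah + bh)
            h[b] = hinf + (h[b] - hinf) * np.exp(-dt * (ah + bh))
            ninf = an / (an + bn)
            n[b] = ninf + (n[b] - ninf) * np.exp(-dt * (an + bn))
            gna_eff = gna * m[b] * m[b] * m[b] * h[b]
            gk_eff = gk * n[b] ** 4
            g_syn_e = ge[b] * syn_scale
            g_syn_i = gi[b] * syn_scale
            gtot = gna_eff + gk_eff + gl + g_syn_e + g_syn_i
            itot = (gna_eff * ena + gk_eff * ek + gl * el
                    + g_syn_e * e_e + g_syn_i * e_i)
            a = dt / cm
            V[b] = (v * (1.0 - 0.5 * a * gtot) + a * itot) / (1.0 + 0.5 * a * gtot)
            ge[b] *= dec_e
            gi[b] *= dec_i
    return iev


@njit(cache=True)
def first_crossing_after(vm_row, start_idx, dt):
    """First upward 0 mV crossing at or after sample ``start_idx``.

    Returns the linearly interpolated crossing time in ms from sample 0, or
    -1.0 when the trace never crosses.  A crossing bracketed by samples
    (k, k+1) counts when k >= start_idx.
    """
    S = vm_row.shape[0]
    for k in range(start_idx, S - 1):
        if vm_row[k] < 0.0 and vm_row[k + 1] >= 0.0:
            frac = -vm_row[k] / (vm_row[k + 1] - vm_row[k])
            return (k + frac) * dt
    return -1.0
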