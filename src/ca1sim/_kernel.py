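"""Compiled inner loop of the cable integrator.

All quantities are in NEURON-like units: mV, ms, absolute capacitance in
mA*ms/mV (= uF * 1e-3), absolute conductances in S, currents in mA.
Gate kinetics are tabulated on a uniform voltage grid; gates advance with
the exponential (Rush-Larsen) rule staggered at half steps, voltages with a
theta-rule tree solve (theta = 0.5: Crank-Nicolson; 1: implicit Euler).
"""

import numpy as np
from numba import njit

# gate kinds
KIND_VTABLE = 0
KIND_CA_HILL = 1
KIND_CA_SHIFTED_VTABLE = 2


@njit(cache=True, fastmath=True)
def _interp_table(table, vmin, dv_inv, v):
    x = (v - vmin) * dv_inv
    n = table.shape[0]
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, fastmath=True)
def run(
    # topology / passive
    parent, g_ax, g_ax_sum, c_abs, g_pas_abs, e_pas,
    # gate tables: (ntab, npts) each
    tab_inf, tab_tau, vmin, dv_inv,
    # gates (flattened over channel instances)
    gate_comp, gate_kind, gate_table, gate_power,
    gate_hill_k, gate_hill_n, gate_tau_const, gate_ca_shift, gate_ca_ref,
    gate_state,
    # channel instances
    inst_comp, inst_gmax, inst_erev, inst_caflux, inst_gate_start,
    inst_ngates,
    # calcium pools
    ca_state, has_ca, ca_rest, ca_tau, ca_gain_abs,
    # step currents: (nstim, 4) columns comp, amp_mA, delay, dur
    stim_comp, stim_amp, stim_delay, stim_dur,
    # synapses
    syn_comp, syn_g1, syn_g2, syn_tau1, syn_tau2, syn_erev,
    ev_time, ev_syn, ev_amp,
    # integration
    v, dt, nsteps, theta, record_idx, record_every,
):
    ncomp = v.shape[0]
    ngate = gate_state.shape[0]
    ninst = inst_comp.shape[0]
    nsyn = syn_comp.shape[0]
    nrec = record_idx.shape[0]
    nout = nsteps // record_every + 1
    out_v = np.empty((nrec, nout))
    out_t = np.empty(nout)
    for r in range(nrec):
        out_v[r, 0] = v[record_idx[r]]
    out_t[0] = 0.0
    iout = 1

    gtot = np.empty(ncomp)
    b = np.empty(ncomp)
    ica = np.empty(ncomp)
    d = np.empty(ncomp)
    rhs = np.empty(ncomp)
    a = np.empty(ncomp)

    dec1 = np.empty(nsyn)
    dec2 = np.empty(nsyn)
    for s in range(nsyn):
        dec1[s] = np.exp(-dt / syn_tau1[s])
        dec2[s] = np.exp(-dt / syn_tau2[s])

    ev_ptr = 0
    nev = ev_time.shape[0]
    status = 0

    for step in range(nsteps):
        t = step * dt
        t_mid = t + 0.5 * dt

        # --- gates (staggered: state lives at half steps) ---------------
        for g in range(ngate):
            c = gate_comp[g]
            kind = gate_kind[g]
            if kind == KIND_CA_HILL:
                caval = ca_state[c]
                can = caval ** gate_hill_n[g]
                xinf = can / (can + gate_hill_k[g] ** gate_hill_n[g])
                tau = gate_tau_const[g]
            else:
                vv = v[c]
                if kind == KIND_CA_SHIFTED_VTABLE:
                    caval = ca_state[c]
                    if caval < 1e-9:
                        caval = 1e-9
                    vv = vv - gate_ca_shift[g] * np.log10(caval / gate_ca_ref[g])
                ti = gate_table[g]
                xinf = _interp_table(tab_inf[ti], vmin, dv_inv, vv)
                tau = _interp_table(tab_tau[ti], vmin, dv_inv, vv)
            if tau < 1e-6:
                gate_state[g] = xinf
            else:
                gate_state[g] += (xinf - gate_state[g]) * (
                    1.0 - np.exp(-dt / tau))

        # --- accumulate membrane conductances ---------------------------
        for c in range(ncomp):
            gtot[c] = g_pas_abs[c]
            b[c] = g_pas_abs[c] * e_pas[c]
            ica[c] = 0.0
        for ii in range(ninst):
            c = inst_comp[ii]
            op = 1.0
            gs = inst_gate_start[ii]
            for j in range(inst_ngates[ii]):
                x = gate_state[gs + j]
                p = gate_power[gs + j]
                for _ in range(p):
                    op *= x
            gabs = inst_gmax[ii] * op
            gtot[c] += gabs
            b[c] += gabs * inst_erev[ii]
            if inst_caflux[ii] > 0.0:
                ica[c] += inst_caflux[ii] * gabs * (v[c] - inst_erev[ii])

        # --- synapses ---------------------------------------------------
        while ev_ptr < nev and ev_time[ev_ptr] < t + dt:
            s = ev_syn[ev_ptr]
            syn_g1[s] += ev_amp[ev_ptr]
            syn_g2[s] += ev_amp[ev_ptr]
            ev_ptr += 1
        for s in range(nsyn):
            syn_g1[s] *= dec1[s]
            syn_g2[s] *= dec2[s]
            gs_abs = syn_g2[s] - syn_g1[s]
            if gs_abs > 0.0:
                c = syn_comp[s]
                gtot[c] += gs_abs
                b[c] += gs_abs * syn_erev[s]

        # --- step currents ----------------------------------------------
        for k in range(stim_comp.shape[0]):
            if stim_delay[k] <= t_mid < stim_delay[k] + stim_dur[k]:
                b[stim_comp[k]] += stim_amp[k]

        # --- theta-rule tree solve --------------------------------------
        for c in range(ncomp):
            d[c] = c_abs[c] / dt + theta * (gtot[c] + g_ax_sum[c])
            rhs[c] = (c_abs[c] / dt) * v[c] \
                - (1.0 - theta) * gtot[c] * v[c] + b[c]
            a[c] = -theta * g_ax[c]
        if theta < 1.0:
            om = 1.0 - theta
            for c in range(1, ncomp):
                p = parent[c]
                f = g_ax[c] * (v[c] - v[p])
                rhs[c] -= om * f
                rhs[p] += om * f
        for c in range(ncomp - 1, 0, -1):
            p = parent[c]
            f = a[c] / d[c]
            d[p] -= f * a[c]
            rhs[p] -= f * rhs[c]
        v[0] = rhs[0] / d[0]
        for c in range(1, ncomp):
            v[c] = (rhs[c] - a[c] * v[parent[c]]) / d[c]

        # --- calcium pools ----------------------------------------------
        for c in range(ncomp):
            if has_ca[c]:
                # dca/dt = -gain * ica - (ca - ca_rest)/tau  (exact update)
                ca_inf = ca_rest[c] - ca_gain_abs[c] * ca_tau[c] * ica[c]
                ca_state[c] += (ca_inf - ca_state[c]) * (
                    1.0 - np.exp(-dt / ca_tau[c]))
                if ca_state[c] < 0.0:
                    ca_state[c] = 0.0

        if (step + 1) % record_every == 0:
            for r in range(nrec):
                vv = v[record_idx[r]]
                out_v[r, iout] = vv
                if not np.isfinite(vv):
                    status = 1
            out_t[iout] = (step + 1) * dt
            iout += 1
            if status != 0:
                break

    return out_t[:iout], out_v[:, :iout], status
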