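"""Numba-compiled integration kernel for the coupled network.

Two compartments per cell (soma with spiking + adaptation, passive dendrite
carrying PF synapses and gap junctions), forward-Euler voltage update with
exact exponential decay of the linear synaptic/adaptation states.  Gap
junctions are ohmic: the current into dendrite i is sum_j g_ij (Vd_j - Vd_i),
evaluated synchronously so the summed GJ current over the network is zero
at every step.

Because the integrate-and-fire soma carries no action-potential waveform,
its contribution to junctional current is restored explicitly: each spike
deposits the charge g_ij * spike_area (the AP's time-integral above
baseline) into every coupled dendrite, reproducing the spikelets through
which Golgi cells synchronize.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
V_BOUND = 200.0     # mV, |V| beyond this aborts the run
E_ADAPT = -90.0     # mV, reversal of the adaptation (AHP) conductance


@njit(cache=False)
def run_network(
    n_steps, dt,
    # per-cell parameters
    c_s, c_d, g_ls, g_ld, g_c, e_l, v_th, v_reset, i_pace, b_w, i_ext,
    ref_steps, f_w,
    # synaptic kinetics (global): decay factors per step and peak-normalized
    # coefficients
    f_md1, f_md2, f_mr, mf_c1, mf_c2,
    f_pd, f_pr, pf_c,
    # gap-junction CSR over dendrites
    gj_indptr, gj_indices, gj_data,
    # input events (sorted by step) and input->cell CSR
    ev_step, ev_id, tgt_ptr, tgt_cell, is_mf,
    # initial conditions
    vs0, vd0,
    max_spikes,
    spike_area,
    # intrinsic somatic noise: OU current, sigma in pA, tau in ms
    noise_sigma, noise_tau, noise_seed,
):
    n = c_s.shape[0]
    vs = vs0.copy()
    vd = vd0.copy()
    vs_new = np.empty(n)
    vd_new = np.empty(n)
    w = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    m1 = np.zeros(n)
    m2 = np.zeros(n)
    mr = np.zeros(n)
    p1 = np.zeros(n)
    pr = np.zeros(n)

    sp_cell = np.empty(max_spikes, dtype=np.int64)
    sp_step = np.empty(max_spikes, dtype=np.int64)
    n_sp = 0

    ev_i = 0
    n_ev = ev_step.shape[0]
    mf_cr = mf_c1 + mf_c2

    # Ornstein-Uhlenbeck intrinsic noise (channel noise / unresolved
    # background synaptic bombardment), exact discrete update
    np.random.seed(noise_seed)
    nz = np.zeros(n)
    a_n = np.exp(-dt / noise_tau)
    c_n = noise_sigma * np.sqrt(1.0 - a_n * a_n)

    for s in range(n_steps):
        sp_start = n_sp
        while ev_i < n_ev and ev_step[ev_i] == s:
            k = ev_id[ev_i]
            if is_mf[k]:
                for t in range(tgt_ptr[k], tgt_ptr[k + 1]):
                    c = tgt_cell[t]
                    m1[c] += 1.0
                    m2[c] += 1.0
                    mr[c] += 1.0
            else:
                for t in range(tgt_ptr[k], tgt_ptr[k + 1]):
                    c = tgt_cell[t]
                    p1[c] += 1.0
                    pr[c] += 1.0
            ev_i += 1

        for i in range(n):
            gmf = mf_c1 * m1[i] + mf_c2 * m2[i] - mf_cr * mr[i]
            gpf = pf_c * (p1[i] - pr[i])
            gj_sum = 0.0
            gj_drive = 0.0
            for jj in range(gj_indptr[i], gj_indptr[i + 1]):
                gj_sum += gj_data[jj]
                gj_drive += gj_data[jj] * vd[gj_indices[jj]]
            # exponential-Euler (conductances frozen over the step):
            # unconditionally stable even under large adaptation/GJ loads
            g_tot_d = g_ld[i] + g_c[i] + gpf + gj_sum
            vinf_d = (g_ld[i] * e_l[i] + g_c[i] * vs[i] + gj_drive) / g_tot_d
            vd_new[i] = vinf_d + (vd[i] - vinf_d) * np.exp(-dt * g_tot_d / c_d[i])

            if refr[i] > 0:
                refr[i] -= 1
                vs_new[i] = v_reset[i]
            else:
                g_tot_s = g_ls[i] + g_c[i] + gmf + w[i]
                vinf_s = (g_ls[i] * e_l[i] + g_c[i] * vd[i] + w[i] * E_ADAPT
                          + i_pace[i] + i_ext[i] + nz[i]) / g_tot_s
                v = vinf_s + (vs[i] - vinf_s) * np.exp(-dt * g_tot_s / c_s[i])
                if v >= v_th[i]:
                    if n_sp < max_spikes:
                        sp_cell[n_sp] = i
                        sp_step[n_sp] = s
                        n_sp += 1
                    w[i] += b_w[i]
                    vs_new[i] = v_reset[i]
                    refr[i] = ref_steps
                else:
                    vs_new[i] = v

            if noise_sigma > 0.0:
                nz[i] = a_n * nz[i] + c_n * np.random.normal()
            w[i] *= f_w
            m1[i] *= f_md1
            m2[i] *= f_md2
            mr[i] *= f_mr
            p1[i] *= f_pd
            pr[i] *= f_pr

        for i in range(n):
            vs[i] = vs_new[i]
            vd[i] = vd_new[i]

        # spikelet transmission: each spike deposits charge g_ij * area into
        # the dendrites of its gap-junction-coupled neighbors
        if spike_area > 0.0:
            for si in range(sp_start, n_sp):
                i = sp_cell[si]
                for jj in range(gj_indptr[i], gj_indptr[i + 1]):
                    j = gj_indices[jj]
                    vd[j] += gj_data[jj] * spike_area / c_d[j]

        if s % 400 == 0:
            for i in range(n):
                if not (-V_BOUND < vs[i] < V_BOUND) or \
                   not (-V_BOUND < vd[i] < V_BOUND):
                    return sp_cell[:n_sp], sp_step[:n_sp], STATUS_DIVERGED, s

    return sp_cell[:n_sp], sp_step[:n_sp], STATUS_OK, n_steps
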