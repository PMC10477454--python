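"""Numba-jitted inner loop of the circuit simulator.

One call integrates the circuit (Euler-Maruyama) for one chunk of steps;
the caller loops over chunks, supplying pre-generated standard-normal
membrane-noise buffers per chunk (numpy's ziggurat sampler is an order of
magnitude faster than drawing normals scalar-wise inside the loop).
Discrete randomness (Poisson generators, stimulus recruitment) uses
numba's global RNG, seeded once on the first chunk, so a run is fully
determined by its two seeds.

Populations: CTX and MSN are Poisson generators (CTX at a fixed baseline
rate plus stimulus-recruited spikes; MSN at baseline or on a stimulus-
locked rate kernel).  STN and GPe are adaptive QIF neurons, either of
which may be substituted by Poisson generators (conductance calibration
stages).  Spike propagation uses per-projection ring buffers of arrival
counts; conductances are pooled per (projection, postsynaptic neuron).

Mutable cross-chunk state lives in caller-owned arrays: neuron states,
conductances, buffers, ``msn_t0``/``active`` (MSN kernel bookkeeping) and
``cursor`` = [n_spikes, stim_pointer, n_active].

Convention: a spike decided during step ``k`` carries spike time
``(k+1) dt`` and arrives ``delay`` steps after that.
"""

import math

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True, fastmath=True)
def run_chunk(
    step0, n_steps, dt, seed,
    # population sizes
    n_ctx, n_msn, n_stn, n_gpe,
    # Poisson per-step probabilities
    p_ctx, p_msn,
    stn_is_poisson, p_stn_sub,
    gpe_is_poisson, p_gpe_sub,
    # GPe aQIF parameters
    kG, vrG, vtG, aG, bG, vpG, cG, dG, IbG, noiseG,
    # STN aQIF parameters
    kS, vrS, vtS, aS, bS, vpS, cS, dS, IbS, noiseS,
    wS, vrtS, atS, btS, dtS,
    # heterogeneous capacitances and states (modified in place)
    stn_C, stn_v, stn_u1, stn_u2,
    gpe_C, gpe_v, gpe_u1,
    # CSR edge lists (indptr over presynaptic index)
    cs_indptr, cs_indices,   # CTX -> STN
    gs_indptr, gs_indices,   # GPe -> STN
    sg_indptr, sg_indices,   # STN -> GPe
    mg_indptr, mg_indices,   # MSN -> GPe
    gg_indptr, gg_indices,   # GPe -> GPe
    ctx_msn,                 # CTX index -> associated MSN index
    # conductance increments (nS)
    G_cs_a, G_cs_n, G_gs, G_sg_a, G_sg_n, G_mg, G_gg,
    # reversal potentials
    E_glu, E_gs, E_g5,
    # per-step decay factors
    dec_ampa, dec_ns, dec_nf, dec_g8, dec_g5,
    # delays in steps
    d_cs, d_gs, d_sg, d_mg, d_gg,
    # arrival ring buffers, shape (delay+1, n_post)
    buf_cs, buf_gs, buf_sg, buf_mg, buf_gg,
    # conductance states
    stn_ga, stn_gns, stn_gnf, stn_gb,
    gpe_ga, gpe_gns, gpe_gnf, gpe_gm, gpe_gg_,
    # stimulation schedule
    stim_steps, stim_s0, s_ctx, sigma_s,
    # MSN kernel lookup (per-step spike probability vs lag since recruitment)
    msn_table,
    # pre-generated standard normals, shape (n_steps, n_stn/n_gpe)
    stn_noise, gpe_noise,
    # recording
    rec_ctx, rec_msn, spike_id, spike_t,
    # optional voltage traces (neuron 0 of each nucleus; len 0 disables)
    trace_stn, trace_gpe,
    # cross-chunk MSN state and cursors [n_spikes, stim_ptr, n_active]
    msn_t0, active, cursor,
):
    if step0 == 0:
        np.random.seed(seed)

    off_msn = n_ctx
    off_stn = n_ctx + n_msn
    off_gpe = off_stn + n_stn

    n_table = len(msn_table)

    cap = len(spike_id)
    ns = cursor[0]
    sp = cursor[1]
    n_active = cursor[2]
    n_stim = len(stim_steps)
    inv_wS = 1.0 / wS
    do_trace_stn = len(trace_stn) > 0 and n_stn > 0 and stn_is_poisson == 0
    do_trace_gpe = len(trace_gpe) > 0 and n_gpe > 0 and gpe_is_poisson == 0
    if step0 == 0:
        if do_trace_stn:
            trace_stn[0] = stn_v[0]
        if do_trace_gpe:
            trace_gpe[0] = gpe_v[0]

    sz_cs = d_cs + 1
    sz_gs = d_gs + 1
    sz_sg = d_sg + 1
    sz_mg = d_mg + 1
    sz_gg = d_gg + 1

    for k in range(n_steps):
        step = step0 + k
        if ns + 4096 > cap:
            cursor[0] = ns
            cursor[1] = sp
            cursor[2] = n_active
            return 1  # overflow: caller retries with larger buffers

        slot_cs = step % sz_cs
        slot_gs = step % sz_gs
        slot_sg = step % sz_sg
        slot_mg = step % sz_mg
        slot_gg = step % sz_gg

        # ---- consume spike arrivals scheduled for this step ----
        if stn_is_poisson == 0:
            for j in range(n_stn):
                c = buf_cs[slot_cs, j]
                if c > 0.0:
                    stn_ga[j] += G_cs_a * c
                    stn_gns[j] += G_cs_n * c
                    stn_gnf[j] += G_cs_n * c
                    buf_cs[slot_cs, j] = 0.0
                c = buf_gs[slot_gs, j]
                if c > 0.0:
                    stn_gb[j] += G_gs * c
                    buf_gs[slot_gs, j] = 0.0
        if gpe_is_poisson == 0:
            for j in range(n_gpe):
                c = buf_sg[slot_sg, j]
                if c > 0.0:
                    gpe_ga[j] += G_sg_a * c
                    gpe_gns[j] += G_sg_n * c
                    gpe_gnf[j] += G_sg_n * c
                    buf_sg[slot_sg, j] = 0.0
                c = buf_mg[slot_mg, j]
                if c > 0.0:
                    gpe_gm[j] += G_mg * c
                    buf_mg[slot_mg, j] = 0.0
                c = buf_gg[slot_gg, j]
                if c > 0.0:
                    gpe_gg_[j] += G_gg * c
                    buf_gg[slot_gg, j] = 0.0

        # ---- stimulus events: recruit CTX generators, arm MSN kernels ----
        while sp < n_stim and stim_steps[sp] == step:
            s0 = stim_s0[sp]
            for i in range(n_ctx):
                x = (s_ctx[i] - s0) / sigma_s
                if np.random.random() < 1.0 / (1.0 + x * x):
                    if rec_ctx == 1:
                        spike_id[ns] = i
                        spike_t[ns] = step + 1
                        ns += 1
                    for e in range(cs_indptr[i], cs_indptr[i + 1]):
                        buf_cs[slot_cs, cs_indices[e]] += 1.0
                    m = ctx_msn[i]
                    if m >= 0:
                        if msn_t0[m] < 0:
                            active[n_active] = m
                            n_active += 1
                        msn_t0[m] = step
            sp += 1

        # ---- baseline CTX Poisson spikes ----
        kc = np.random.binomial(n_ctx, p_ctx)
        for _ in range(kc):
            i = np.random.randint(0, n_ctx)
            if rec_ctx == 1:
                spike_id[ns] = i
                spike_t[ns] = step + 1
                ns += 1
            for e in range(cs_indptr[i], cs_indptr[i + 1]):
                buf_cs[slot_cs, cs_indices[e]] += 1.0

        # ---- MSN spikes: kernel-driven actives, baseline for the rest ----
        ia = 0
        while ia < n_active:
            m = active[ia]
            lag = step - msn_t0[m]
            if lag >= n_table:
                msn_t0[m] = -1
                n_active -= 1
                active[ia] = active[n_active]
                continue
            if np.random.random() < msn_table[lag]:
                if rec_msn == 1:
                    spike_id[ns] = off_msn + m
                    spike_t[ns] = step + 1
                    ns += 1
                for e in range(mg_indptr[m], mg_indptr[m + 1]):
                    buf_mg[slot_mg, mg_indices[e]] += 1.0
            ia += 1
        km = np.random.binomial(n_msn - n_active, p_msn)
        for _ in range(km):
            m = np.random.randint(0, n_msn)
            if msn_t0[m] >= 0:
                continue
            if rec_msn == 1:
                spike_id[ns] = off_msn + m
                spike_t[ns] = step + 1
                ns += 1
            for e in range(mg_indptr[m], mg_indptr[m + 1]):
                buf_mg[slot_mg, mg_indices[e]] += 1.0

        # ---- STN: Poisson substitute or aQIF dynamics ----
        if stn_is_poisson == 1:
            ks = np.random.binomial(n_stn, p_stn_sub)
            for _ in range(ks):
                j = np.random.randint(0, n_stn)
                spike_id[ns] = off_stn + j
                spike_t[ns] = step + 1
                ns += 1
                for e in range(sg_indptr[j], sg_indptr[j + 1]):
                    buf_sg[slot_sg, sg_indices[e]] += 1.0
        else:
            for j in range(n_stn):
                v = stn_v[j]
                u1 = stn_u1[j]
                u2 = stn_u2[j]
                I = stn_ga[j] * (E_glu - v) + stn_gb[j] * (E_gs - v) + IbS
                gd = stn_gns[j] - stn_gnf[j]
                if gd != 0.0:
                    B = 1.0 / (1.0 + 0.28 * math.exp(-0.062 * v))
                    I += B * gd * (E_glu - v)
                vn = (v + dt * (kS * (v - vrS) * (v - vtS)
                                - u1 - wS * u2 + I) / stn_C[j]
                      + noiseS * stn_noise[k, j])
                u1n = u1 + dt * aS * (bS * (v - vrS) - u1)
                if v < vrtS:
                    u2n = u2 + dt * atS * (btS * (v - vrtS) - u2)
                else:
                    u2n = u2 - dt * atS * u2
                U = 1.0 / (wS * abs(u2n) + inv_wS)
                if vn >= vpS + U * u2n:
                    spike_id[ns] = off_stn + j
                    spike_t[ns] = step + 1
                    ns += 1
                    vn = cS - U * u2n
                    u1n += dS
                    u2n += dtS
                    for e in range(sg_indptr[j], sg_indptr[j + 1]):
                        buf_sg[slot_sg, sg_indices[e]] += 1.0
                stn_v[j] = vn
                stn_u1[j] = u1n
                stn_u2[j] = u2n
            if do_trace_stn:
                trace_stn[step + 1] = stn_v[0]

        # ---- GPe: Poisson substitute or aQIF dynamics ----
        if gpe_is_poisson == 1:
            kg = np.random.binomial(n_gpe, p_gpe_sub)
            for _ in range(kg):
                j = np.random.randint(0, n_gpe)
                spike_id[ns] = off_gpe + j
                spike_t[ns] = step + 1
                ns += 1
                for e in range(gs_indptr[j], gs_indptr[j + 1]):
                    buf_gs[slot_gs, gs_indices[e]] += 1.0
        else:
            for j in range(n_gpe):
                v = gpe_v[j]
                u1 = gpe_u1[j]
                I = (gpe_ga[j] * (E_glu - v)
                     + (gpe_gm[j] + gpe_gg_[j]) * (E_g5 - v) + IbG)
                gd = gpe_gns[j] - gpe_gnf[j]
                if gd != 0.0:
                    B = 1.0 / (1.0 + 0.28 * math.exp(-0.062 * v))
                    I += B * gd * (E_glu - v)
                vn = (v + dt * (kG * (v - vrG) * (v - vtG) - u1 + I) / gpe_C[j]
                      + noiseG * gpe_noise[k, j])
                u1n = u1 + dt * aG * (bG * (v - vrG) - u1)
                if vn >= vpG:
                    spike_id[ns] = off_gpe + j
                    spike_t[ns] = step + 1
                    ns += 1
                    vn = cG
                    u1n += dG
                    for e in range(gs_indptr[j], gs_indptr[j + 1]):
                        buf_gs[slot_gs, gs_indices[e]] += 1.0
                    for e in range(gg_indptr[j], gg_indptr[j + 1]):
                        buf_gg[slot_gg, gg_indices[e]] += 1.0
                gpe_v[j] = vn
                gpe_u1[j] = u1n
            if do_trace_gpe:
                trace_gpe[step + 1] = gpe_v[0]

        # ---- exponential decay of all pooled conductances ----
        if stn_is_poisson == 0:
            for j in range(n_stn):
                stn_ga[j] *= dec_ampa
                stn_gns[j] *= dec_ns
                stn_gnf[j] *= dec_nf
                stn_gb[j] *= dec_g8
        if gpe_is_poisson == 0:
            for j in range(n_gpe):
                gpe_ga[j] *= dec_ampa
                gpe_gns[j] *= dec_ns
                gpe_gnf[j] *= dec_nf
                gpe_gm[j] *= dec_g5
                gpe_gg_[j] *= dec_g5

    cursor[0] = ns
    cursor[1] = sp
    cursor[2] = n_active
    return 0
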