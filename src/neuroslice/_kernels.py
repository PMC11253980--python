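"""Numba kernels for the hot loops: synapse formation and network dynamics.

The synapse kernel consumes one Mersenne-Twister stream per presynaptic
neuron (``np.random.seed`` inside the jitted function reproduces
``numpy.random.RandomState``), with Bernoulli trials ordered by axon cell
and then by ascending target index.  The brute-force validation path in
:mod:`neuroslice.topology` consumes the exact same stream in the exact same
order, so the two produce bitwise-identical networks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# SCP lookup shared by the fast path and the brute-force oracle


@njit(cache=False)
def scp_lookup(d, table, dr):
    """Piecewise-linear interpolation of a tabulated SCP at distance d (μm)."""
    x = d / dr
    i = int(x)
    if i >= table.shape[0] - 1:
        return 0.0
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


# ---------------------------------------------------------------------------
# Synapse establishment


@njit(cache=False)
def synapses_for_axon(owner, cells, soma_xy, dend_r, soma_radius, L,
                      bin_start, bin_items, nbx, bin_size,
                      table, dr, seed):
    """Bernoulli synapse trials for one axon against all dendritic fields.

    For every 1 μm axon cell and every neuron j ≠ owner whose annulus
    (soma_radius, dend_r[j]] contains the cell center (minimal-image
    distance on the torus), one uniform draw is consumed; successes are
    counted into w[owner, j].  ``bin_start/bin_items`` is a coverage index:
    neuron j is registered in every bin its dendritic disk touches, so each
    cell only inspects its own bin.  Targets are visited in ascending j
    within each cell so the stream order is reproducible.  ``table`` holds
    the genotype's SCP on a regular ``dr`` grid.

    Returns (target_ids, contact_counts) for targets with ≥ 1 contact.
    """
    np.random.seed(seed)
    n = soma_xy.shape[0]
    counts = np.zeros(n, dtype=np.int32)
    max_cand = 8192
    cand_j = np.empty(max_cand, dtype=np.int64)
    cand_d = np.empty(max_cand, dtype=np.float64)

    for ci in range(cells.shape[0]):
        cx = cells[ci, 0] + 0.5
        cy = cells[ci, 1] + 0.5
        bx = int(cx / bin_size)
        by = int(cy / bin_size)
        if bx >= nbx:
            bx = nbx - 1
        if by >= nbx:
            by = nbx - 1
        nc = 0
        b = bx * nbx + by
        for k in range(bin_start[b], bin_start[b + 1]):
            j = bin_items[k]
            if j == owner:
                continue
            dx = cx - soma_xy[j, 0]
            dx -= L * np.floor(dx / L + 0.5)
            dy = cy - soma_xy[j, 1]
            dy -= L * np.floor(dy / L + 0.5)
            d = np.sqrt(dx * dx + dy * dy)
            if d > soma_radius and d <= dend_r[j]:
                if nc >= max_cand:
                    raise ValueError("candidate buffer overflow")
                cand_j[nc] = j
                cand_d[nc] = d
                nc += 1
        # insertion sort by target index: trial order must be deterministic
        for p in range(1, nc):
            jj = cand_j[p]
            dd = cand_d[p]
            q = p - 1
            while q >= 0 and cand_j[q] > jj:
                cand_j[q + 1] = cand_j[q]
                cand_d[q + 1] = cand_d[q]
                q -= 1
            cand_j[q + 1] = jj
            cand_d[q + 1] = dd
        for p in range(nc):
            prob = scp_lookup(cand_d[p], table, dr)
            u = np.random.random()
            if u < prob:
                counts[cand_j[p]] += 1

    n_hit = 0
    for j in range(n):
        if counts[j] > 0:
            n_hit += 1
    js = np.empty(n_hit, dtype=np.int64)
    ws = np.empty(n_hit, dtype=np.int64)
    k = 0
    for j in range(n):
        if counts[j] > 0:
            js[k] = j
            ws[k] = counts[j]
            k += 1
    return js, ws


# ---------------------------------------------------------------------------
# Izhikevich network dynamics


@njit(cache=False)
def simulate_network(indptr, indices, weights, is_exc,
                     cell_a, cell_b, cell_c, cell_d, v_thr,
                     g_ampa_inc, g_gaba_inc, g_ext_inc,
                     decay_ampa, decay_gaba, decay_ext,
                     vr_ampa, vr_gaba, vr_ext,
                     lam_dt, ii_scale, dt, n_steps, n_transient_steps,
                     delay_steps, seed, max_spikes, record_id):
    """Forward-Euler Izhikevich network with delayed exponential synapses.

    ``indptr/indices/weights`` is a CSR adjacency by presynaptic row
    (w[i, j]: i presynaptic → j postsynaptic, integer contact counts).
    A spike of neuron m at step t increments, at step t + delay_steps, the
    AMPA (m excitatory) or GABA (m inhibitory) conductance of every
    postsynaptic j by g·w[m, j]; GABA increments onto inhibitory targets are
    additionally scaled by ``ii_scale``.  External Poisson events (rate
    ``lam_dt`` per neuron per step) add ``g_ext_inc`` without delay.
    Conductances decay exactly, g ← g·exp(−dt/τ), each step.

    Returns (spike_steps, spike_ids, n_spikes, v0, status, g_trace) where
    status = 0 on success, 1 on numerical blowup (the offending neuron id is
    then in n_spikes... see wrapper), and g_trace records the three
    conductances of neuron ``record_id`` (all steps) when record_id ≥ 0.
    """
    np.random.seed(seed)
    n = is_exc.shape[0]
    v = np.empty(n)
    u = np.empty(n)
    for i in range(n):
        v[i] = -70.0 + 10.0 * np.random.random()
        u[i] = cell_b[i] * v[i]
    g_a = np.zeros(n)
    g_g = np.zeros(n)
    g_e = np.zeros(n)
    nslot = delay_steps + 1
    pend_a = np.zeros((nslot, n))
    pend_g = np.zeros((nslot, n))

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int32)
    n_sp = 0
    if record_id >= 0:
        g_trace = np.zeros((3, n_steps))
    else:
        g_trace = np.zeros((3, 1))

    status = 0
    bad_neuron = -1
    for t in range(n_steps):
        slot = t % nslot
        for i in range(n):
            g_a[i] += pend_a[slot, i]
            g_g[i] += pend_g[slot, i]
            pend_a[slot, i] = 0.0
            pend_g[slot, i] = 0.0
        if lam_dt > 0.0:
            for i in range(n):
                k = np.random.poisson(lam_dt)
                if k > 0:
                    g_e[i] += k * g_ext_inc
        if record_id >= 0:
            g_trace[0, t] = g_a[record_id]
            g_trace[1, t] = g_g[record_id]
            g_trace[2, t] = g_e[record_id]
        dslot = (t + delay_steps) % nslot
        for i in range(n):
            vi = v[i]
            ui = u[i]
            # intrinsic terms explicit; synaptic conductance term implicit
            # (g can transiently exceed 1/dt during population bursts, where
            # a fully explicit step would overshoot past the reversals)
            gsum = g_a[i] + g_g[i] + g_e[i]
            num = (vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui)
                   + dt * (g_a[i] * vr_ampa + g_g[i] * vr_gaba
                           + g_e[i] * vr_ext))
            vn = num / (1.0 + dt * gsum)
            un = ui + dt * cell_a[i] * (cell_b[i] * vi - ui)
            if not (-1e9 < vn < 1e9):
                status = 1
                bad_neuron = i
                break
            if vn >= v_thr:
                if t >= n_transient_steps:
                    if n_sp >= max_spikes:
                        status = 2
                        break
                    spike_steps[n_sp] = t
                    spike_ids[n_sp] = i
                    n_sp += 1
                # synaptic delivery after the delay
                exc = is_exc[i]
                for kk in range(indptr[i], indptr[i + 1]):
                    j = indices[kk]
                    w = weights[kk]
                    if exc:
                        pend_a[dslot, j] += g_ampa_inc * w
                    else:
                        gg = g_gaba_inc * w
                        if not is_exc[j]:
                            gg *= ii_scale
                        pend_g[dslot, j] += gg
                vn = cell_c[i]
                un = un + cell_d[i]
            v[i] = vn
            u[i] = un
        if status != 0:
            break
        for i in range(n):
            g_a[i] *= decay_ampa
            g_g[i] *= decay_gaba
            g_e[i] *= decay_ext
    return (spike_steps[:n_sp], spike_ids[:n_sp], n_sp, bad_neuron, status,
            g_trace)
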