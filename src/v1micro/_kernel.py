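"""Numba hot loop for the network integration.

One step advances, in order: (1) external Poisson arrivals are written into
the delay ring buffer's current slot, (2) the per-neuron, per-channel summed
weighted gates G decay exactly by exp(-dt/tau) and absorb the slot's
arrivals, (3) the membrane potential of every non-refractory neuron is
advanced by classical RK4 with the gates decaying piecewise-exponentially
within the step (sub-stage conductances use half- and full-step decay
factors), and (4) threshold crossings emit spikes whose weights are scheduled
into the ring buffer after their per-edge delay (grid-rounded, minimum one
step).

Channel layout (second gate axis): 0..3 are presynaptic classes
Pyr/PV/SOM/VIP, 4 is background drive, 5 is feedforward drive.  Reversal
potentials per channel enter through ``erev``; the synaptic current on a
neuron is -sum_c G_c (V - E_c), so excitatory channels (E = 0 mV) depolarize
and inhibitory channels (E = -70 mV) pull V toward -70 mV.
"""

import numpy as np
from numba import njit

#: kernel exit codes
OK = 0
NONFINITE = 1
SPIKE_OVERFLOW = 2

N_CHANNELS = 6
CH_BACKGROUND = 4
CH_FEEDFORWARD = 5


@njit(cache=True)
def run_network(
    n_steps,
    dt,
    buf_len,
    class_idx,  # (N,) int8
    inv_tau_m,  # (N,) 1/ms
    e_leak,  # mV
    v_thr,
    v_reset,
    inv_cm,  # 1/pF
    decay,  # (N, 6) exp(-dt/tau)
    half_decay,  # (N, 6) exp(-dt/(2 tau))
    erev,  # (6,) mV
    ref_steps,  # (N,) int64
    indptr,  # (N+1,) CSR over presynaptic id
    post,  # (E,) int32
    weight,  # (E,)
    delay_steps,  # (E,) int64, >= 1
    bg_lam,  # (N,) expected background arrivals per step
    bg_g,
    ff_indptr,  # (F+1,)
    ff_post,  # int32
    ff_g,
    ff_lam,  # expected arrivals per fiber per step
    onset_step,
    seed,
    max_spikes,
    g_const,  # (N,) constant excitatory conductance clamp, nS
    monitor,  # neuron id whose V trajectory is recorded, or -1
):
    np.random.seed(seed)
    n = class_idx.shape[0]
    n_fibers = ff_indptr.shape[0] - 1

    gates = np.zeros((n, N_CHANNELS))
    buf = np.zeros((buf_len, n, N_CHANNELS))
    v = np.full(n, e_leak)
    ref = np.zeros(n, dtype=np.int64)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    n_spikes = 0
    v_trace = np.empty(n_steps + 1 if monitor >= 0 else 0)
    if monitor >= 0:
        v_trace[0] = v[monitor]

    for t in range(n_steps):
        slot = t % buf_len

        # external Poisson arrivals for this step
        for i in range(n):
            k = np.random.poisson(bg_lam[i])
            if k > 0:
                buf[slot, i, CH_BACKGROUND] += bg_g * k
        if t >= onset_step:
            for f in range(n_fibers):
                k = np.random.poisson(ff_lam)
                if k > 0:
                    for e in range(ff_indptr[f], ff_indptr[f + 1]):
                        buf[slot, ff_post[e], CH_FEEDFORWARD] += ff_g * k

        # exact exponential gate decay + arrival increments
        for i in range(n):
            for c in range(N_CHANNELS):
                gates[i, c] = gates[i, c] * decay[i, c] + buf[slot, i, c]
                buf[slot, i, c] = 0.0

        # membrane integration
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
                continue

            a0 = g_const[i]
            b0 = 0.0
            ah = g_const[i]
            bh = 0.0
            a1 = g_const[i]
            b1 = 0.0
            for c in range(N_CHANNELS):
                g0 = gates[i, c]
                gh = g0 * half_decay[i, c]
                g1 = g0 * decay[i, c]
                a0 += g0
                ah += gh
                a1 += g1
                b0 += g0 * erev[c]
                bh += gh * erev[c]
                b1 += g1 * erev[c]

            itm = inv_tau_m[i]
            vi = v[i]
            k1 = -(vi - e_leak) * itm - (a0 * vi - b0) * inv_cm
            v2 = vi + 0.5 * dt * k1
            k2 = -(v2 - e_leak) * itm - (ah * v2 - bh) * inv_cm
            v3 = vi + 0.5 * dt * k2
            k3 = -(v3 - e_leak) * itm - (ah * v3 - bh) * inv_cm
            v4 = vi + dt * k3
            k4 = -(v4 - e_leak) * itm - (a1 * v4 - b1) * inv_cm
            vn = vi + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

            if not np.isfinite(vn):
                return spike_id[:n_spikes], spike_t[:n_spikes], NONFINITE, v_trace

            if vn >= v_thr:
                if n_spikes >= max_spikes:
                    return spike_id[:n_spikes], spike_t[:n_spikes], SPIKE_OVERFLOW, v_trace
                spike_id[n_spikes] = i
                spike_t[n_spikes] = (t + 1) * dt
                n_spikes += 1
                v[i] = v_reset
                ref[i] = ref_steps[i]
                ch = class_idx[i]
                for e in range(indptr[i], indptr[i + 1]):
                    arrive = (t + 1 + delay_steps[e]) % buf_len
                    buf[arrive, post[e], ch] += weight[e]
            else:
                v[i] = vn

        if monitor >= 0:
            v_trace[t + 1] = v[monitor]

    return spike_id[:n_spikes], spike_t[:n_spikes], OK, v_trace
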