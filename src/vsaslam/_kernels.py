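"""Hot inner loops for neural-tier simulation.

These are jitted with numba when available and fall back to pure-Python
(identical semantics, much slower) otherwise.  Everything here operates on
pre-tuned arrays; tuning and decoder solving live in :mod:`vsaslam.nef`.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True, fastmath=True)
def lif_population_run(values, enc_sc, bias, decoders, dt, tau_rc, tau_ref, ksyn):
    """Spiking LIF run of one population over a value sequence.

    values: (T, dim) input per step; enc_sc: (n, dim) gain-scaled encoders;
    decoders: (n, dim_out).  Returns the tau-syn-filtered decoded output
    (T, dim_out).  Spike amplitude is 1/dt.
    """
    T, dim = values.shape
    n = enc_sc.shape[0]
    dim_out = decoders.shape[1]
    out = np.zeros((T, dim_out), dtype=values.dtype)
    voltage = np.zeros(n, dtype=values.dtype)
    refractory = np.zeros(n, dtype=values.dtype)
    y = np.zeros(dim_out, dtype=values.dtype)
    amp = 1.0 / dt
    for t in range(T):
        dec = np.zeros(dim_out, dtype=values.dtype)
        for i in range(n):
            J = bias[i]
            for k in range(dim):
                J += enc_sc[i, k] * values[t, k]
            ref = refractory[i] - dt
            delta = dt - ref
            if delta < 0.0:
                delta = 0.0
            elif delta > dt:
                delta = dt
            refractory[i] = ref if ref > 0.0 else 0.0
            decay = math.exp(-delta / tau_rc)
            vv = voltage[i] * decay + (1.0 - decay) * J
            if vv > 1.0:
                # exact within-step spike time keeps realized rates unbiased
                t_spike = dt + tau_rc * math.log1p(-(vv - 1.0) / (J - 1.0))
                refractory[i] = tau_ref + t_spike
                vv = 0.0
                for k in range(dim_out):
                    dec[k] += decoders[i, k] * amp
            voltage[i] = vv
        for k in range(dim_out):
            y[k] += ksyn * (dec[k] - y[k])
            out[t, k] = y[k]
    return out


@njit(cache=True, fastmath=True)
def vco_chunk_rate(xf, y, enc_sc, bias, dec, omega_seq, ucorr, tau_rc, tau_ref, ksyn):
    """Advance a bank of velocity-controlled oscillator populations (rate tier).

    Each of the ``nv`` populations represents (normalized frequency, Re, Im)
    of one Fourier coefficient.  The recurrent connection decodes the
    stabilized-oscillator dynamics map (tau*f + identity on Re/Im); a second
    decode reads out (Re, Im).  Both pass through the same low-pass synapse.

    xf: (nv, 3) filtered represented state; y: (nv, 2) filtered output;
    enc_sc: (nv, n, 3) gain-scaled encoders; bias: (nv, n); dec: (nv, n, 4)
    as [rec_Re, rec_Im, out_Re, out_Im]; omega_seq: (K, nv) normalized
    frequency input per step; ucorr: (nv, 2) constant correction current
    (already scaled by tau*gain).
    """
    K = omega_seq.shape[0]
    nv, n = bias.shape
    for t in range(K):
        for v in range(nv):
            r0 = 0.0
            r1 = 0.0
            o0 = 0.0
            o1 = 0.0
            x0 = xf[v, 0]
            x1 = xf[v, 1]
            x2 = xf[v, 2]
            for i in range(n):
                J = (
                    enc_sc[v, i, 0] * x0
                    + enc_sc[v, i, 1] * x1
                    + enc_sc[v, i, 2] * x2
                    + bias[v, i]
                )
                if J > 1.0:
                    rate = 1.0 / (tau_ref - tau_rc * math.log1p(-1.0 / J))
                    r0 += dec[v, i, 0] * rate
                    r1 += dec[v, i, 1] * rate
                    o0 += dec[v, i, 2] * rate
                    o1 += dec[v, i, 3] * rate
            xf[v, 0] += ksyn * (omega_seq[t, v] - xf[v, 0])
            xf[v, 1] += ksyn * (r0 + ucorr[v, 0] - xf[v, 1])
            xf[v, 2] += ksyn * (r1 + ucorr[v, 1] - xf[v, 2])
            y[v, 0] += ksyn * (o0 - y[v, 0])
            y[v, 1] += ksyn * (o1 - y[v, 1])


@njit(cache=True, fastmath=True)
def vco_chunk_spiking(
    xf,
    y,
    voltage,
    refractory,
    enc_sc,
    bias,
    dec,
    omega_seq,
    ucorr,
    dt,
    tau_rc,
    tau_ref,
    ksyn,
):
    """Spiking-tier twin of :func:`vco_chunk_rate` (spike amplitude 1/dt).

    Voltage follows a zero-order-hold exponential update; a refractory
    counter clamps integration for ``tau_ref`` after each spike.
    """
    K = omega_seq.shape[0]
    nv, n = bias.shape
    amp = 1.0 / dt
    full_decay = math.exp(-dt / tau_rc)
    for t in range(K):
        for v in range(nv):
            r0 = 0.0
            r1 = 0.0
            o0 = 0.0
            o1 = 0.0
            x0 = xf[v, 0]
            x1 = xf[v, 1]
            x2 = xf[v, 2]
            for i in range(n):
                J = (
                    enc_sc[v, i, 0] * x0
                    + enc_sc[v, i, 1] * x1
                    + enc_sc[v, i, 2] * x2
                    + bias[v, i]
                )
                ref = refractory[v, i]
                if ref <= 0.0:
                    decay = full_decay
                else:
                    ref -= dt
                    delta = dt - ref
                    if delta < 0.0:
                        delta = 0.0
                    elif delta > dt:
                        delta = dt
                    decay = math.exp(-delta / tau_rc)
                    refractory[v, i] = ref if ref > 0.0 else 0.0
                vv = voltage[v, i] * decay + (1.0 - decay) * J
                if vv > 1.0:
                    # exact within-step spike time (unbiased realized rates)
                    t_spike = dt + tau_rc * math.log1p(-(vv - 1.0) / (J - 1.0))
                    refractory[v, i] = tau_ref + t_spike
                    vv = 0.0
                    r0 += dec[v, i, 0] * amp
                    r1 += dec[v, i, 1] * amp
                    o0 += dec[v, i, 2] * amp
                    o1 += dec[v, i, 3] * amp
                voltage[v, i] = vv
            xf[v, 0] += ksyn * (omega_seq[t, v] - xf[v, 0])
            xf[v, 1] += ksyn * (r0 + ucorr[v, 0] - xf[v, 1])
            xf[v, 2] += ksyn * (r1 + ucorr[v, 1] - xf[v, 2])
            y[v, 0] += ksyn * (o0 - y[v, 0])
            y[v, 1] += ksyn * (o1 - y[v, 1])


@njit(cache=True, fastmath=True)
def lif_spike_positions_run(values, enc_sc, bias, dt, tau_rc, tau_ref, neuron_ids):
    """Spiking run recording spike (step, neuron) pairs for selected neurons.

    Returns an (n_events, 2) int64 array of (time-step index, position in
    ``neuron_ids``).  Used for firing-map analysis of recorded populations.
    """
    T, dim = values.shape
    n = enc_sc.shape[0]
    voltage = np.zeros(n, dtype=values.dtype)
    refractory = np.zeros(n, dtype=values.dtype)
    max_events = T * len(neuron_ids)  # upper bound is loose but bounded by rates
    events = np.empty((max_events, 2), dtype=np.int64)
    count = 0
    for t in range(T):
        for i in range(n):
            J = bias[i]
            for k in range(dim):
                J += enc_sc[i, k] * values[t, k]
            delta = dt - refractory[i]
            if delta < 0.0:
                delta = 0.0
            elif delta > dt:
                delta = dt
            decay = math.exp(-delta / tau_rc)
            voltage[i] = voltage[i] * decay + (1.0 - decay) * J
            refractory[i] -= dt
            if refractory[i] < 0.0:
                refractory[i] = 0.0
            if voltage[i] > 1.0:
                voltage[i] = 0.0
                refractory[i] = tau_ref
                for j in range(len(neuron_ids)):
                    if neuron_ids[j] == i and count < max_events:
                        events[count, 0] = t
                        events[count, 1] = j
                        count += 1
    return events[:count]
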