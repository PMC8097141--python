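"""Numba-compiled integration kernels.

The hybrid (continuous flow + discrete reset) neuron model is integrated
with fixed-step forward Euler.  The reset rule is applied at most once per
step, immediately after the Euler update, and the spike timestamp is the
time at the end of the step on which the cutoff was reached.
"""

import numpy as np
from numba import njit

__all__ = ["integrate_single", "integrate_network"]


@njit(cache=True)
def integrate_single(Cm, vr, vt, vpeak, a, b, c, d, klow, khigh,
                     V0, u0, I, dt):
    """Integrate one two-regime quadratic adaptive neuron.

    Parameters are scalars; ``I`` is the per-step applied current (pA),
    one value per integration step.  Returns the sampled membrane
    potential and recovery variable (length ``len(I) + 1``, including the
    initial state) and the spike times in ms.
    """
    n = I.shape[0]
    V = np.empty(n + 1)
    u = np.empty(n + 1)
    V[0] = V0
    u[0] = u0
    spikes = np.empty(n, np.float64)
    ns = 0
    v = V0
    w = u0
    for i in range(n):
        k = klow if v <= vt else khigh
        dv = (k * (v - vr) * (v - vt) - w + I[i]) / Cm
        dw = a * (b * (v - vr) - w)
        v = v + dt * dv
        w = w + dt * dw
        if v >= vpeak:
            spikes[ns] = (i + 1) * dt
            ns += 1
            v = c
            w = w + d
        V[i + 1] = v
        u[i + 1] = w
    return V, u, spikes[:ns]


@njit(cache=True)
def _first_spike_step(Cm, vr, vt, vpeak, a, b, c, d, klow, khigh,
                      V0, u0, I_const, dt, n_steps):
    """Return the step index of the first spike under constant current,
    or -1 if the cell stays subthreshold.  Cheap helper for sweeps."""
    v = V0
    w = u0
    for i in range(n_steps):
        k = klow if v <= vt else khigh
        v = v + dt * ((k * (v - vr) * (v - vt) - w + I_const) / Cm)
        w = w + dt * (a * (b * (v - vr) - w))
        if v >= vpeak:
            return i + 1
        if not np.isfinite(v):
            return -2
    return -1


@njit(cache=True)
def integrate_network(Cm, vr, vt, vpeak, a, b, c, d, klow, khigh,
                      V0, u0,
                      indptr, targets, weights, syn_is_inh,
                      tau_e, tau_i, E_e, E_i,
                      drive_mean, noise, noise_stride,
                      dt, n_steps, max_spikes):
    """Integrate a recurrent network of two-regime quadratic neurons.

    Synapses are conductance-based single exponentials: each presynaptic
    spike increments the target's excitatory or inhibitory conductance by
    the edge weight (nS); conductances decay with ``tau_e`` / ``tau_i``.
    ``noise`` holds per-cell piecewise-constant fluctuation currents, one
    column per ``noise_stride`` integration steps.

    Returns (status, offending_cell, offending_time, spike_cells,
    spike_times); status 0 = ok, 1 = non-finite state encountered,
    2 = spike buffer overflow.
    """
    n = Cm.shape[0]
    V = V0.copy()
    u = u0.copy()
    ge = np.zeros(n)
    gi = np.zeros(n)
    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    spike_cells = np.empty(max_spikes, np.int64)
    spike_times = np.empty(max_spikes, np.float64)
    ns = 0
    for step in range(n_steps):
        t = (step + 1) * dt
        col = step // noise_stride
        for i in range(n):
            v = V[i]
            k = klow[i] if v <= vt[i] else khigh[i]
            I_in = (drive_mean[i] + noise[i, col]
                    + ge[i] * (E_e - v) + gi[i] * (E_i - v))
            V[i] = v + dt * ((k * (v - vr[i]) * (v - vt[i]) - u[i] + I_in)
                             / Cm[i])
            u[i] = u[i] + dt * (a[i] * (b[i] * (v - vr[i]) - u[i]))
        for i in range(n):
            ge[i] *= dec_e
            gi[i] *= dec_i
        for i in range(n):
            if V[i] >= vpeak[i]:
                if ns >= max_spikes:
                    return 2, i, t, spike_cells[:ns], spike_times[:ns]
                spike_cells[ns] = i
                spike_times[ns] = t
                ns += 1
                V[i] = c[i]
                u[i] += d[i]
                for e in range(indptr[i], indptr[i + 1]):
                    tgt = targets[e]
                    if syn_is_inh[e]:
                        gi[tgt] += weights[e]
                    else:
                        ge[tgt] += weights[e]
        if step % 256 == 0:
            for i in range(n):
                if not np.isfinite(V[i]):
                    return 1, i, t, spike_cells[:ns], spike_times[:ns]
    return 0, -1, 0.0, spike_cells[:ns], spike_times[:ns]
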