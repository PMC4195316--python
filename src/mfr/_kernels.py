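"""Numba JIT kernels for the integrate-and-fire time-stepping loops.

Units inside the kernels: time ms, voltage mV, current pA, capacitance pF,
conductance nS (pA/pF = mV/ms, nS*mV = pA, pF/nS = ms).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lif_passive(drive, decay, rm, e_r, v_th, v0):
    """Leaky IF with fixed leak conductance (no resonant or inhibitory term).

    Exponential-Euler update with drive held constant over each step:
    v_inf = e_r + rm*I with rm in mV/pA, decay = exp(-dt/tau_m).
    Returns (spike step indices, final v).
    """
    n = drive.size
    v = v0
    out = np.empty(n, np.int64)
    m = 0
    for k in range(n):
        vinf = e_r + rm * drive[k]
        v = vinf + (v - vinf) * decay
        if v >= v_th:
            out[m] = k
            m += 1
            v = e_r
    return out[:m], v


@njit(cache=True)
def if_conductance(drive, dt, c, g_l, e_r, v_th, g_b_ns, tau_b, g_i, e_i, v0, b0):
    """General IF step with spike-triggered resonant conductance g_b*b.

    b jumps by 1 at each spike and decays exponentially with tau_b; the
    resonant and inhibitory terms are conductances toward e_r and e_i.
    Exponential Euler with the conductance state frozen within a step.
    Returns (spike step indices, final v, final b).
    """
    n = drive.size
    v = v0
    b = b0
    decay_b = np.exp(-dt / tau_b)
    out = np.empty(n, np.int64)
    m = 0
    for k in range(n):
        gb = g_b_ns * b
        g = g_l + gb + g_i
        vinf = ((g_l + gb) * e_r + g_i * e_i + drive[k]) / g
        v = vinf + (v - vinf) * np.exp(-dt * g / c)
        b = b * decay_b
        if v >= v_th:
            out[m] = k
            m += 1
            v = e_r
            b = b + 1.0
    return out[:m], v, b


@njit(cache=True)
def ideal_encoder(rate, dt, acc0):
    """Leak-free unit-threshold integrator over a rate signal (spikes/s).

    Negative rates are clipped to zero (rectification).  At most one spike is
    emitted per step; surplus accumulation carries over, so spike times stay
    strictly increasing even for extreme rates.
    Returns (spike step indices, final accumulator).
    """
    n = rate.size
    acc = acc0
    scale = dt * 1e-3  # spikes/s * ms -> spikes
    out = np.empty(n, np.int64)
    m = 0
    for k in range(n):
        r = rate[k]
        if r > 0.0:
            acc += r * scale
        if acc >= 1.0:
            out[m] = k
            m += 1
            acc -= 1.0
    return out[:m], acc
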