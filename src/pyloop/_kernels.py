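"""Forward-Euler integration kernels.

The gating ODE dm/dt = (m_inf(V) - m)/tau_m(V) and the single-compartment
membrane equation are integrated with the fixed-step first-order forward
Euler method throughout the package.  The inner loops are compiled with
numba when available; a pure-Python fallback keeps the package importable
without it (slow, but correct).
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def h_gate_series(v, dt, v_half, v_slope, tau_max, tau_v_half, tau_v_slope, m0):
    """Forward-Euler trajectory of the h-type activation gate under V(t).

    Returns m[i] = gate state after the update driven by sample v[i],
    starting from m0.  Clamped to [0, 1] after every step.
    """
    n = v.shape[0]
    out = np.empty(n)
    m = m0
    for i in range(n):
        vi = v[i]
        minf = 1.0 / (1.0 + np.exp((vi - v_half) / v_slope))
        tau = tau_max / np.cosh((vi - tau_v_half) / tau_v_slope)
        m = m + dt * (minf - m) / tau
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        out[i] = m
    return out


@njit(cache=True)
def a_gate_series(v, dt, m_v_half, m_v_slope, tau_act, h_v_half, h_v_slope, tau_inact, m0, h0):
    """Forward-Euler trajectories of A-current activation m and inactivation h."""
    n = v.shape[0]
    m_out = np.empty(n)
    h_out = np.empty(n)
    m = m0
    h = h0
    for i in range(n):
        vi = v[i]
        minf = 1.0 / (1.0 + np.exp((vi - m_v_half) / m_v_slope))
        hinf = 1.0 / (1.0 + np.exp((vi - h_v_half) / h_v_slope))
        m = m + dt * (minf - m) / tau_act
        h = h + dt * (hinf - h) / tau_inact
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        m_out[i] = m
        h_out[i] = h
    return m_out, h_out


@njit(cache=True)
def dynamic_clamp_current(v, dt, v_half, v_slope, tau_max, tau_v_half, tau_v_slope, m0, g_max, e_rev):
    """Causal dynamic-clamp stream: I[i] uses the gate state from sample i-1."""
    n = v.shape[0]
    out = np.empty(n)
    m = m0
    for i in range(n):
        vi = v[i]
        out[i] = g_max * m * (vi - e_rev)
        minf = 1.0 / (1.0 + np.exp((vi - v_half) / v_slope))
        tau = tau_max / np.cosh((vi - tau_v_half) / tau_v_slope)
        m = m + dt * (minf - m) / tau
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
    return out


@njit(cache=True)
def rebound_cycle(
    v0,
    mh0,
    ma0,
    ha0,
    dt,
    n_inh,
    n_total,
    c_nF,
    g_leak,
    e_leak,
    g_h,
    e_h,
    h_v_half,
    h_v_slope,
    h_tau_max,
    h_tau_v_half,
    h_tau_v_slope,
    g_a,
    e_k,
    a_v_half,
    a_v_slope,
    a_tau_act,
    i_v_half,
    i_v_slope,
    a_tau_inact,
    g_syn,
    e_syn,
    threshold,
):
    """One pacemaker cycle of the single-compartment rebound neuron.

    Synaptic inhibition is a square conductance pulse occupying the first
    ``n_inh`` samples.  Returns the end-of-cycle state plus the index of the
    first suprathreshold crossing after inhibition ends (-1 if none), the
    number of suprathreshold samples after inhibition, and the minimum
    voltage reached (for diagnostics).
    """
    v = v0
    mh = mh0
    ma = ma0
    ha = ha0
    cross = -1
    n_above = 0
    v_min = v0
    for i in range(n_total):
        gs = g_syn if i < n_inh else 0.0
        i_h = g_h * mh * (v - e_h)
        i_a = g_a * ma * ma * ma * ha * (v - e_k)
        i_l = g_leak * (v - e_leak)
        i_s = gs * (v - e_syn)
        v = v + dt * (-(i_h + i_a + i_l + i_s)) / c_nF
        if v < v_min:
            v_min = v
        minf = 1.0 / (1.0 + np.exp((v - h_v_half) / h_v_slope))
        tau = h_tau_max / np.cosh((v - h_tau_v_half) / h_tau_v_slope)
        mh = mh + dt * (minf - mh) / tau
        if mh < 0.0:
            mh = 0.0
        elif mh > 1.0:
            mh = 1.0
        am = 1.0 / (1.0 + np.exp((v - a_v_half) / a_v_slope))
        ah = 1.0 / (1.0 + np.exp((v - i_v_half) / i_v_slope))
        ma = ma + dt * (am - ma) / a_tau_act
        ha = ha + dt * (ah - ha) / a_tau_inact
        if ma < 0.0:
            ma = 0.0
        elif ma > 1.0:
            ma = 1.0
        if ha < 0.0:
            ha = 0.0
        elif ha > 1.0:
            ha = 1.0
        if i >= n_inh and v >= threshold:
            n_above += 1
            if cross < 0:
                cross = i
    return v, mh, ma, ha, cross, n_above, v_min
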