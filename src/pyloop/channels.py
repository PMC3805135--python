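"""Conductance models of the two opposing subthreshold currents.

I_h is the hyperpolarization-activated inward current (HCN-mediated).  It is
modelled exactly as in a dynamic-clamp conductance injection: a single
first-order Boltzmann gate m with

    I_h = G_max * m * (V - E_rev),       dm/dt = (m_inf(V) - m) / tau_m(V),
    m_inf(V) = 1 / (1 + exp((V - V_half) / V_slope)),

with E_rev = -35 mV and a bell-shaped tau_m(V).  A positive V_slope makes
the gate open with hyperpolarization.

I_A is the transient (A-type, Kv4-mediated) potassium current, modelled in
the classic m^3 h form: a fast depolarization-activated gate cubed times a
slow inactivation gate.  Hyperpolarization removes resting inactivation
("deinactivation"), which is what the -90 mV clamp prepulse exploits.

Integration is fixed-step forward Euler everywhere (see `_kernels`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .core import SampledTrace, ValidationError

__all__ = [
    "HChannelParams",
    "AChannelParams",
    "GateState",
    "gate_steady_state",
    "gate_tau",
    "advance_gate",
    "channel_current",
    "dynamic_clamp_stream",
    "h_gate_trajectory",
    "a_gate_trajectory",
]


@dataclass(frozen=True)
class HChannelParams:
    """I_h model parameters.

    Defaults (V_half = -95 mV, V_slope = +8 mV, tau_m peaking at 800 ms near
    V_half) are assumptions consistent with currents that reach steady state
    within a 4 s hyperpolarizing step; they are fixtures, not measured values.
    """

    g_max: float = 0.1  # uS
    e_rev: float = -35.0  # mV
    v_half: float = -95.0  # mV
    v_slope: float = 8.0  # mV, positive: activated by hyperpolarization
    tau_max: float = 800.0  # ms, peak of the bell
    tau_v_half: float = -95.0  # mV, centre of the bell
    tau_v_slope: float = 20.0  # mV, width of the bell

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValidationError("HChannelParams.g_max must be >= 0")
        if self.v_slope == 0:
            raise ValidationError("HChannelParams.v_slope must be non-zero")
        if self.tau_max <= 0 or self.tau_v_slope == 0:
            raise ValidationError("HChannelParams tau parameters must give tau_m(V) > 0")

    def tau_m(self, v: float | np.ndarray) -> float | np.ndarray:
        return self.tau_max / np.cosh((np.asarray(v, dtype=float) - self.tau_v_half) / self.tau_v_slope)

    def m_inf(self, v: float | np.ndarray) -> float | np.ndarray:
        return gate_steady_state(v, self.v_half, self.v_slope)

    def scaled(self, factor: float) -> "HChannelParams":
        """Same channel with g_max multiplied by ``factor``."""
        return replace(self, g_max=self.g_max * factor)


@dataclass(frozen=True)
class AChannelParams:
    """I_A model parameters (m^3 h kinetics; defaults are fixtures)."""

    g_max: float = 0.5  # uS
    e_rev: float = -80.0  # mV (assumed E_K)
    act_v_half: float = -30.0  # mV
    act_v_slope: float = -10.0  # mV, negative: activated by depolarization
    tau_act: float = 10.0  # ms
    inact_v_half: float = -60.0  # mV
    inact_v_slope: float = 6.0  # mV, positive: deinactivated by hyperpolarization
    tau_inact: float = 80.0  # ms

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValidationError("AChannelParams.g_max must be >= 0")
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise ValidationError("AChannelParams taus must be > 0")
        if self.act_v_slope == 0 or self.inact_v_slope == 0:
            raise ValidationError("AChannelParams slopes must be non-zero")

    def m_inf(self, v):
        return gate_steady_state(v, self.act_v_half, self.act_v_slope)

    def h_inf(self, v):
        return gate_steady_state(v, self.inact_v_half, self.inact_v_slope)

    def scaled(self, factor: float) -> "AChannelParams":
        return replace(self, g_max=self.g_max * factor)


@dataclass
class GateState:
    """Gating-variable values; ``h`` is only meaningful for the A-current."""

    m: float = 0.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValidationError("GateState values must lie in [0, 1]")


def gate_steady_state(v, v_half, v_slope):
    """First-order Boltzmann steady state m_inf = 1/(1 + exp((V - V_half)/V_slope))."""
    if v_slope == 0:
        raise ValidationError("v_slope must be non-zero")
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / v_slope))


def gate_tau(v, params: HChannelParams) -> float:
    return float(params.tau_m(v))


def steady_state(params, v: float) -> GateState:
    """Gate state fully relaxed at voltage ``v``."""
    if isinstance(params, HChannelParams):
        return GateState(m=float(params.m_inf(v)), h=1.0)
    return GateState(m=float(params.m_inf(v)), h=float(params.h_inf(v)))


def advance_gate(state: GateState, v: float, dt: float, params) -> GateState:
    """One forward-Euler step of the gating ODE at voltage ``v``.

    Values are clamped to [0, 1] after the update.  A step larger than the
    local time constant is outside the stability region of forward Euler; it
    is allowed (the clamp keeps the state bounded) but a warning is logged.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if isinstance(params, HChannelParams):
        tau = float(params.tau_m(v))
        if dt > tau:
            warnings.warn(f"forward-Euler step dt={dt} ms exceeds tau_m({v} mV)={tau:.3g} ms", stacklevel=2)
        m = state.m + dt * (float(params.m_inf(v)) - state.m) / tau
        return GateState(m=min(1.0, max(0.0, m)), h=state.h)
    if dt > min(params.tau_act, params.tau_inact):
        warnings.warn(f"forward-Euler step dt={dt} ms exceeds an I_A time constant", stacklevel=2)
    m = state.m + dt * (float(params.m_inf(v)) - state.m) / params.tau_act
    h = state.h + dt * (float(params.h_inf(v)) - state.h) / params.tau_inact
    return GateState(m=min(1.0, max(0.0, m)), h=min(1.0, max(0.0, h)))


def channel_current(state: GateState, v, params) -> float | np.ndarray:
    """Instantaneous channel current in nA (uS * mV = nA).

    I_h = g_max * m * (V - E_rev); I_A = g_max * m^3 * h * (V - E_rev).
    Linear in g_max; zero at the reversal potential.
    """
    if isinstance(params, HChannelParams):
        return params.g_max * state.m * (np.asarray(v, dtype=float) - params.e_rev)
    return params.g_max * state.m**3 * state.h * (np.asarray(v, dtype=float) - params.e_rev)


def h_gate_trajectory(voltage: np.ndarray, dt: float, params: HChannelParams, m0: float) -> np.ndarray:
    """Forward-Euler gate trajectory of the h-gate under a sampled voltage."""
    return _kernels.h_gate_series(
        np.ascontiguousarray(voltage, dtype=float),
        float(dt),
        params.v_half,
        params.v_slope,
        params.tau_max,
        params.tau_v_half,
        params.tau_v_slope,
        float(m0),
    )


def a_gate_trajectory(voltage: np.ndarray, dt: float, params: AChannelParams, m0: float, h0: float):
    return _kernels.a_gate_series(
        np.ascontiguousarray(voltage, dtype=float),
        float(dt),
        params.act_v_half,
        params.act_v_slope,
        params.tau_act,
        params.inact_v_half,
        params.inact_v_slope,
        params.tau_inact,
        float(m0),
        float(h0),
    )


def channel_current_series(voltage: SampledTrace, params, state0: GateState | None = None) -> np.ndarray:
    """Channel current along a voltage trace (gate integrated per sample)."""
    v = voltage.values
    if state0 is None:
        state0 = steady_state(params, float(v[0]))
    if isinstance(params, HChannelParams):
        m = h_gate_trajectory(v, voltage.dt_ms, params, state0.m)
        return params.g_max * m * (v - params.e_rev)
    m, h = a_gate_trajectory(v, voltage.dt_ms, params, state0.m, state0.h)
    return params.g_max * m**3 * h * (v - params.e_rev)


def dynamic_clamp_stream(voltage: SampledTrace, params: HChannelParams, scale: float = 1.0) -> SampledTrace:
    """Offline dynamic-clamp engine: per-sample gating on a measured voltage.

    The injected current at sample n is computed from the gate state carried
    over from sample n-1 (causal), then the gate is advanced with the voltage
    at sample n:  I = scale * g_max * m * (V - E_rev).
    """
    if voltage.kind != "voltage":
        raise ValidationError("dynamic_clamp_stream expects a voltage trace")
    v = np.ascontiguousarray(voltage.values, dtype=float)
    m0 = float(params.m_inf(v[0]))
    out = _kernels.dynamic_clamp_current(
        v,
        voltage.dt_ms,
        params.v_half,
        params.v_slope,
        params.tau_max,
        params.tau_v_half,
        params.tau_v_slope,
        m0,
        scale * params.g_max,
        params.e_rev,
    )
    return SampledTrace(out, voltage.dt_ms, "nA", "current", t0_ms=voltage.t0_ms)
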