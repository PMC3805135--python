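"""Gating kinetics, channel currents and the dynamic-clamp stream."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import pyloop as pl
from pyloop.channels import channel_current_series, h_gate_trajectory, steady_state
from pyloop.core import SampledTrace, ValidationError


class TestGateSteadyState:
    def test_half_activation(self):
        assert pl.gate_steady_state(-95.0, -95.0, 8.0) == 0.5

    def test_hyperpolarized_asymptote(self):
        assert pl.gate_steady_state(-500.0, -95.0, 8.0) == pytest.approx(1.0)

    def test_printed_value(self):
        # 1/(1 + e^(-25/8)) at -120 mV
        assert pl.gate_steady_state(-120.0, -95.0, 8.0) == pytest.approx(0.9580, abs=2e-4)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValidationError):
            pl.gate_steady_state(-95.0, -95.0, 0.0)


class TestAdvanceGate:
    H = pl.HChannelParams(g_max=0.1)

    def test_steady_state_is_fixed_point(self):
        m_inf = float(self.H.m_inf(-80.0))
        out = pl.advance_gate(pl.GateState(m=m_inf), -80.0, 0.05, self.H)
        assert out.m == pytest.approx(m_inf, abs=1e-12)

    def test_relaxation_reaches_632pct_at_tau(self):
        v = -120.0
        tau = float(self.H.tau_m(v))
        state = pl.GateState(m=0.0)
        dt = 0.05
        for _ in range(int(round(tau / dt))):
            state = pl.advance_gate(state, v, dt, self.H)
        assert state.m / float(self.H.m_inf(v)) == pytest.approx(1 - np.exp(-1), rel=5e-3)

    def test_forward_euler_first_order_convergence(self):
        """Halving dt halves the max deviation from the closed-form relaxation."""
        v = -120.0
        tau, m_inf = float(self.H.tau_m(v)), float(self.H.m_inf(v))
        def max_err(dt):
            n = int(round(2 * tau / dt))
            t = np.arange(1, n + 1) * dt
            exact = m_inf * (1.0 - np.exp(-t / tau))
            m, out = 0.0, np.empty(n)
            for i in range(n):
                m += dt * (m_inf - m) / tau
                out[i] = m
            return np.max(np.abs(out - exact))
        e1, e2 = max_err(tau / 50), max_err(tau / 100)
        assert e1 / e2 == pytest.approx(2.0, rel=0.1)

    def test_closed_form_match_at_tau_over_100(self):
        """Forward Euler at dt = tau/100 stays within 1% of the exponential."""
        v, dt_frac = -100.0, 100
        tau, m_inf = float(self.H.tau_m(v)), float(self.H.m_inf(v))
        dt = tau / dt_frac
        n = int(5 * dt_frac)
        v_arr = np.full(n, v)
        m = h_gate_trajectory(v_arr, dt, self.H, 0.0)
        exact = m_inf * (1.0 - np.exp(-np.arange(1, n + 1) * dt / tau))
        assert np.max(np.abs(m - exact)) <= 0.01 * m_inf

    def test_unstable_dt_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="exceeds"):
            out = pl.advance_gate(pl.GateState(m=0.0), -95.0, 5000.0, self.H)
        assert 0.0 <= out.m <= 1.0


class TestChannelCurrent:
    def test_zero_at_reversal(self):
        h = pl.HChannelParams(g_max=0.1)
        assert pl.channel_current(pl.GateState(m=0.7), h.e_rev, h) == 0.0

    def test_ohmic_arithmetic(self):
        h = pl.HChannelParams(g_max=0.1)
        assert pl.channel_current(pl.GateState(m=0.5), -85.0, h) == pytest.approx(-2.5)

    def test_linear_in_gmax(self):
        a = pl.AChannelParams(g_max=0.5)
        s = pl.GateState(m=0.6, h=0.4)
        assert pl.channel_current(s, 0.0, a.scaled(3.0)) == pytest.approx(3 * pl.channel_current(s, 0.0, a))

    def test_iv_sweep_round_trip_with_tevc(self):
        """In-silico clamp of the model channel recovers its own G_max within 2%."""
        ih = pl.HChannelParams(g_max=0.1)
        episodes = pl.generate_clamp_trace([ih], (0.05, -50.0), pl.ih_protocol())
        vs, gs = [], []
        for ep in episodes:
            amp, _ = pl.measure_ih_peak(ep.current, ep.step_window)
            vs.append(ep.test_level)
            gs.append(pl.to_conductance(amp, ep.test_level, ih.e_rev))
        fit = pl.fit_boltzmann(vs, gs)
        assert fit.gmax == pytest.approx(ih.g_max, rel=0.02)
        assert fit.v_half == pytest.approx(ih.v_half, abs=1.0)

    @given(
        v=hnp.arrays(np.float64, st.integers(min_value=10, max_value=300),
                     elements=st.floats(min_value=-130.0, max_value=60.0)),
    )
    @settings(max_examples=30, deadline=None)
    def test_gates_stay_bounded_for_any_voltage_trace(self, v):
        trace = SampledTrace(v, 0.05, "mV", "voltage")
        ih = pl.HChannelParams(g_max=0.1)
        m = h_gate_trajectory(trace.values, trace.dt_ms, ih, 0.5)
        assert np.all((m >= 0.0) & (m <= 1.0))


class TestDynamicClampStream:
    H = pl.HChannelParams(g_max=0.1)

    def test_constant_voltage_converges_to_steady_state(self):
        v = -110.0
        n = int(6 * float(self.H.tau_m(v)) / 0.05)
        trace = SampledTrace(np.full(n, v), 0.05, "mV", "voltage")
        out = pl.dynamic_clamp_stream(trace, self.H)
        expected = self.H.g_max * float(self.H.m_inf(v)) * (v - self.H.e_rev)
        assert out.values[-1] == pytest.approx(expected, rel=0.01)

    def test_zero_scale_is_identically_zero(self):
        trace = SampledTrace(np.linspace(-80, -40, 1000), 0.05, "mV", "voltage")
        assert np.all(pl.dynamic_clamp_stream(trace, self.H, scale=0.0).values == 0.0)

    def test_linear_in_scale(self):
        rng = np.random.default_rng(2)
        v = -70.0 + 15.0 * np.sin(np.linspace(0, 20, 4000)) + rng.normal(0, 1, 4000)
        trace = SampledTrace(v, 0.05, "mV", "voltage")
        full = pl.dynamic_clamp_stream(trace, self.H, scale=1.0)
        scaled = pl.dynamic_clamp_stream(trace, self.H, scale=0.06)
        assert np.allclose(scaled.values, 0.06 * full.values)
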