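"""Synthetic-data generator: periodicity, preset recovery, clamp traces."""
import numpy as np
import pytest

import pyloop as pl
from pyloop.core import ValidationError


class TestNetworkRecording:
    def test_zero_jitter_is_exactly_periodic(self, baseline):
        pd_t, lp_t = pl.generate_network_recording(baseline, 20000.0, seed=1)
        pd_bursts = pl.detect_bursts(pd_t, max_isi=150.0)
        assert len(pd_bursts) == 20
        periods = np.diff(pd_bursts.last_spike)
        assert np.allclose(periods, 1000.0)

    def test_same_seed_reproducible(self, jittered_baseline):
        a = pl.generate_network_recording(jittered_baseline, 20000.0, seed=5)
        b = pl.generate_network_recording(jittered_baseline, 20000.0, seed=5)
        assert np.array_equal(a[0].times_ms, b[0].times_ms)
        assert np.array_equal(a[1].times_ms, b[1].times_ms)

    def test_jittered_mean_period_converges(self, baseline):
        """Independent onset jitter leaves the mean period within 1% over >= 60 cycles."""
        preset = pl.baseline_preset(cycle_jitter_sd=20.0)
        pd_t, _ = pl.generate_network_recording(preset, 70000.0, seed=7)
        periods = np.diff(pl.detect_bursts(pd_t, 150.0).last_spike)
        assert len(periods) >= 60
        assert abs(np.mean(periods) - 1000.0) < 10.0

    def test_da_scaled_burst_duration_ratio(self, baseline, da):
        """Measured LP burst-duration fold tracks the 30% dopamine reduction."""
        scaled = pl.apply_da_preset(baseline, da)
        _, lp_base = pl.generate_network_recording(baseline, 30000.0, seed=2)
        _, lp_da = pl.generate_network_recording(scaled, 30000.0, seed=3)
        c_base = np.mean(pl.detect_bursts(lp_base, 150.0).duration)
        c_da = np.mean(pl.detect_bursts(lp_da, 100.0).duration)
        assert c_da / c_base == pytest.approx(da.lp_burst_factor, rel=0.02)

    def test_too_short_duration_rejected(self, baseline):
        with pytest.raises(ValidationError):
            pl.generate_network_recording(baseline, 5000.0, seed=0)

    def test_invalid_preset_names_field(self):
        with pytest.raises(ValidationError, match="lp_on_delay"):
            pl.baseline_preset(lp_on_delay=800.0)  # delay + burst >= period


class TestDAPreset:
    def test_period_scaling(self, baseline, da):
        assert pl.apply_da_preset(baseline, da).cycle_period == pytest.approx(900.0)

    def test_identity_preset_is_noop(self, baseline):
        ident = pl.da_preset(period_factor=1.0, lp_burst_factor=1.0, lp_on_phase_factor=1.0, isi_factor=1.0)
        assert pl.apply_da_preset(baseline, ident) == baseline

    def test_phase_factor_sets_delay(self, baseline, da):
        # base phase 0.25, factor 0.8, new period 900 -> delay 180 ms
        assert pl.apply_da_preset(baseline, da).lp_on_delay == pytest.approx(180.0)


class TestCommandWaveform:
    def test_lumped_spike_step_width(self):
        """Six 2 ms spikes lumped into one 12 ms step to +40 mV per cycle."""
        wf = pl.CommandWaveform(spike_mode="lumped", spike_count=6, spike_width=2.0, n_cycles=2).validate()
        trace = pl.generate_command(wf, dt=0.05)
        cycle = trace.values[: int(1000 / 0.05)]
        assert np.sum(cycle == 40.0) * 0.05 == pytest.approx(12.0)

    def test_duty_cycle_and_duration(self):
        wf = pl.CommandWaveform(spike_mode="none", n_cycles=3, cycle_period=1000.0, step_duration=300.0).validate()
        trace = pl.generate_command(wf, dt=0.05)
        assert trace.duration_ms == pytest.approx(3000.0)
        assert np.mean(trace.values == wf.peak_voltage) == pytest.approx(0.30)

    def test_patterned_gap_equals_spike_isi(self):
        wf = pl.CommandWaveform(
            spike_mode="patterned", spike_count=6, spike_width=2.0, spike_isi=0.66 * 50.0, n_cycles=1
        ).validate()
        trace = pl.generate_command(wf, dt=0.05)
        at_peak = np.flatnonzero(trace.values == wf.spike_peak)
        onsets = at_peak[np.flatnonzero(np.diff(at_peak) > 1) + 1]
        gaps = np.diff(np.concatenate([[at_peak[0]], onsets])) * 0.05 - 2.0
        assert np.allclose(gaps, 0.66 * 50.0)

    def test_patterned_overflow_rejected(self):
        with pytest.raises(ValidationError, match="fit"):
            pl.CommandWaveform(spike_mode="patterned", spike_count=10, spike_isi=50.0, step_duration=300.0).validate()


class TestClampTraces:
    def test_pure_leak_is_ohmic_and_flat(self):
        proto = pl.StepProtocol(holding=-50.0, steps=((-50.0, 100.0, -120.0, 500.0),))
        ep = pl.generate_clamp_trace([], (0.05, -50.0), proto)[0]
        test = ep.current.window(*ep.step_window).values
        assert np.allclose(test, 0.05 * (-120.0 + 50.0))  # -3.5 nA

    def test_ih_late_current_approaches_steady_state(self):
        ih = pl.HChannelParams(g_max=0.1)
        ep = pl.generate_clamp_trace([ih], (0.05, -50.0), pl.ih_protocol())[-1]  # -120 mV step
        late = np.mean(ep.current.values[-100:])
        expected = 0.05 * (-120.0 + 50.0) + 0.1 * float(ih.m_inf(-120.0)) * (-120.0 + 35.0)
        assert late == pytest.approx(expected, rel=0.01)

    def test_noisy_trace_fit_recovers_noise_free_amplitude(self):
        """Exponential fit on a noisy trace recovers the noise-free steady state within 2%."""
        ih = pl.HChannelParams(g_max=0.1)
        clean = pl.generate_clamp_trace([ih], (0.05, -50.0), pl.ih_protocol())[-1]
        noisy = pl.generate_clamp_trace([ih], (0.05, -50.0), pl.ih_protocol(), noise_sd=0.05, seed=3)[-1]
        amp_clean, _ = pl.measure_ih_peak(clean.current, clean.step_window)
        amp_noisy, _ = pl.measure_ih_peak(noisy.current, noisy.step_window)
        assert amp_noisy == pytest.approx(amp_clean, rel=0.02)
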