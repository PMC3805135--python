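"""Voltage-clamp measurement chain: exponential, leak subtraction, Boltzmann."""
import numpy as np
import pytest

import pyloop as pl
from pyloop.core import SampledTrace, ValidationError


def _exp_trace(amp=-5.0, tau=800.0, offset=-2.0, dt=0.05, t_end=4000.0, noise=0.0, seed=0):
    t = np.arange(0.0, t_end, dt)
    y = offset + amp * (1.0 - np.exp(-t / tau))
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, size=t.shape)
    return SampledTrace(y, dt, "nA", "current")


class TestIhProtocol:
    def test_steps_match_published_series(self):
        proto = pl.ih_protocol()
        levels = [s[2] for s in proto.steps]
        assert levels == [-60.0, -70.0, -80.0, -90.0, -100.0, -110.0, -120.0]
        assert all(s[3] == 4000.0 for s in proto.steps)
        assert proto.holding == -50.0 and proto.inter_step == 6000.0


class TestMeasureIhPeak:
    def test_back_extrapolation_recovers_construction(self):
        trace = _exp_trace()
        amp, fit = pl.measure_ih_peak(trace, (0.0, 4000.0))
        assert amp == pytest.approx(-5.0, rel=1e-3)
        assert fit.tau == pytest.approx(800.0, rel=1e-3)
        assert fit.offset == pytest.approx(-2.0, rel=1e-3)

    def test_noisy_amplitude_within_2pct(self):
        amp, _ = pl.measure_ih_peak(_exp_trace(noise=0.05, seed=1), (0.0, 4000.0))
        assert amp == pytest.approx(-5.0, rel=0.02)

    def test_methods_agree_with_5_tau_of_data(self):
        """exp-fit and peak-minus-leak agree within 3% given >= 5 tau of data."""
        trace = _exp_trace(tau=700.0, t_end=4000.0, noise=0.02, seed=2)
        amp_fit, _ = pl.measure_ih_peak(trace, (0.0, 4000.0), method="exp_fit")
        amp_pml, fit = pl.measure_ih_peak(trace, (0.0, 4000.0), method="peak_minus_leak")
        assert fit is None
        assert amp_pml == pytest.approx(amp_fit, rel=0.03)

    def test_rmse_gate_recommends_fallback(self):
        rng = np.random.default_rng(3)
        trace = _exp_trace()
        trace.values += 0.5 * np.sin(2 * np.pi * np.arange(len(trace)) * 0.05 / 700.0)  # slow oscillation artifact
        with pytest.raises(pl.MeasurementError, match="peak_minus_leak"):
            pl.measure_ih_peak(trace, (0.0, 4000.0), rmse_max_nA=0.1)


class TestMeasureIaPeak:
    def test_identical_traces_give_zero(self):
        trace = _exp_trace()
        assert pl.measure_ia_peak(trace, trace) == pytest.approx(0.0, abs=1e-12)

    def test_known_peak_recovered_within_2pct(self):
        """Difference-current peak matches the noise-free generator truth."""
        ia = pl.AChannelParams(g_max=0.5)
        leak = (0.05, -50.0)
        clean_t = pl.generate_clamp_trace([ia], leak, pl.ia_test_protocol())[0]
        clean_l = pl.generate_clamp_trace([ia], leak, pl.ia_leak_protocol())[0]
        oracle = np.max(clean_t.current.values - clean_l.current.values)
        noisy_t = pl.generate_clamp_trace([ia], leak, pl.ia_test_protocol(), noise_sd=0.05, seed=3)[0]
        noisy_l = pl.generate_clamp_trace([ia], leak, pl.ia_leak_protocol(), noise_sd=0.05, seed=4)[0]
        peak = pl.measure_ia_peak(noisy_t.current, noisy_l.current, step_window=noisy_t.step_window)
        assert peak == pytest.approx(oracle, rel=0.02)

    def test_da_scaling_recovered(self):
        """Scaling the generator G_A by 0.81 yields a measured peak ratio 0.81 +- 0.03."""
        leak = (0.05, -50.0)
        def peak(factor, seed):
            ia = pl.AChannelParams(g_max=0.5).scaled(factor)
            t = pl.generate_clamp_trace([ia], leak, pl.ia_test_protocol(), noise_sd=0.05, seed=seed)[0]
            l = pl.generate_clamp_trace([ia], leak, pl.ia_leak_protocol(), noise_sd=0.05, seed=seed + 7)[0]
            return pl.measure_ia_peak(t.current, l.current, step_window=t.step_window)
        assert peak(0.81, 1) / peak(1.0, 2) == pytest.approx(0.81, abs=0.03)

    def test_length_mismatch_rejected(self):
        trace = _exp_trace()
        with pytest.raises(ValidationError):
            pl.measure_ia_peak(trace, SampledTrace(trace.values[:-10], 0.05, "nA", "current"))


class TestToConductance:
    def test_arithmetic(self):
        assert pl.to_conductance(-8.5, -120.0, -35.0) == pytest.approx(0.1)
        assert pl.to_conductance(0.0, -120.0, -35.0) == 0.0

    def test_round_trip_identity(self):
        g = pl.to_conductance(-4.25, -100.0, -35.0)
        assert g * (-100.0 + 35.0) == pytest.approx(-4.25)

    def test_reversal_rejected(self):
        with pytest.raises(ValidationError):
            pl.to_conductance(1.0, -35.0, -35.0)


class TestFitBoltzmann:
    VOLTS = np.arange(-60.0, -130.0, -10.0)

    @staticmethod
    def _curve(v, gmax=0.1, v_half=-95.0, v_slope=8.0):
        return gmax / (1.0 + np.exp((v - v_half) / v_slope))

    def test_noise_free_exact_recovery(self):
        fit = pl.fit_boltzmann(self.VOLTS, self._curve(self.VOLTS))
        assert fit.gmax == pytest.approx(0.1, rel=1e-3)
        assert fit.v_half == pytest.approx(-95.0, abs=0.1)
        assert fit.v_slope == pytest.approx(8.0, rel=1e-3)

    def test_noisy_v_half_within_2mV(self):
        """5% multiplicative noise over 7 voltages: v_half recovered within 2 mV on average."""
        errs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            g = self._curve(self.VOLTS) * (1.0 + rng.normal(0.0, 0.05, size=len(self.VOLTS)))
            errs.append(abs(pl.fit_boltzmann(self.VOLTS, g).v_half + 95.0))
        assert np.mean(errs) < 2.0

    def test_hyperpolarization_activated_slope_positive(self):
        fit = pl.fit_boltzmann(self.VOLTS, self._curve(self.VOLTS))
        assert fit.v_slope > 0  # conductance grows with hyperpolarization

    def test_recovery_improves_as_noise_vanishes(self):
        """Mean |gmax error| decreases monotonically across three noise levels."""
        def mean_err(noise):
            errs = []
            for seed in range(10):
                rng = np.random.default_rng(100 + seed)
                g = self._curve(self.VOLTS) * (1.0 + rng.normal(0.0, noise, size=len(self.VOLTS)))
                errs.append(abs(pl.fit_boltzmann(self.VOLTS, g).gmax - 0.1))
            return np.mean(errs)
        errors = [mean_err(n) for n in (0.10, 0.03, 0.0)]
        assert errors[0] > errors[1] > errors[2]
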