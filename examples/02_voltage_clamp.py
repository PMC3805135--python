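"""In-silico two-electrode voltage clamp of the model currents.

Forward-simulates the I_h activation protocol (4 s steps, -60 to -120 mV)
on a known h-channel plus leak, measures each step by single-exponential
back-extrapolation, converts to conductance and fits the Boltzmann
activation curve; then measures peak I_A by -40 mV-prepulse leak
subtraction.  The fitted G_max/V_half should recover the generator's
parameters (0.1 uS, -95 mV), and the I_A peak ratio the 0.81 modulation.
"""
import pyloop as pl

leak = (0.05, -50.0)

ih = pl.HChannelParams(g_max=0.1, v_half=-95.0, v_slope=8.0)
episodes = pl.generate_clamp_trace([ih], leak, pl.ih_protocol(), noise_sd=0.05, seed=1)
voltages, conductances = [], []
for ep in episodes:
    amplitude, fit = pl.measure_ih_peak(ep.current, ep.step_window, method="exp_fit")
    voltages.append(ep.test_level)
    conductances.append(pl.to_conductance(amplitude, ep.test_level, ih.e_rev))
    print(f"step {ep.test_level:6.0f} mV: I_h = {amplitude:7.3f} nA  tau = {fit.tau:5.0f} ms")

boltz = pl.fit_boltzmann(voltages, conductances)
print(f"Boltzmann fit: G_max = {boltz.gmax:.4f} uS (true 0.1), "
      f"V_half = {boltz.v_half:.1f} mV (true -95), V_slope = {boltz.v_slope:.2f} mV")

ia = pl.AChannelParams(g_max=0.5)
for factor in (1.0, 0.81):
    test = pl.generate_clamp_trace([ia.scaled(factor)], leak, pl.ia_test_protocol(), noise_sd=0.05, seed=3)[0]
    lk = pl.generate_clamp_trace([ia.scaled(factor)], leak, pl.ia_leak_protocol(), noise_sd=0.05, seed=4)[0]
    peak = pl.measure_ia_peak(test.current, lk.current, step_window=test.step_window)
    print(f"peak I_A at +60 mV (g x {factor}): {peak:.2f} nA")
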