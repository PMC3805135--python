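"""The minimal pacemaker-driven rebound neuron: phase advance and recovery.

A single-compartment neuron with leak, I_A and I_h receives a periodic
inhibitory pulse.  At t = 2 min a dopamine event reduces g_A to 81% and
shortens the pacemaker period by 10%: the firing phase advances ~20%.
The dopamine-enabled rule then lowers I_h G_max in response to the
changed activity until the phase recovers.  With the dynamic-clamp
add-back (cancelling the metaplastic I_h change from dopamine + 10 min)
the phase stays advanced.
"""
import pyloop as pl

for addback in (False, True):
    cfg = pl.default_rebound_config(da_onset_min=2.0, dynamic_clamp_addback=addback)
    result = pl.run_network_experiment(cfg, duration_min=45.0)
    phase = result.series("phase_fold")
    gmax = result.series("gmax_fold")
    label = "with add-back" if addback else "closed loop  "
    samples = [0, 2, 5, 12, 20, 30, 44]
    print(f"{label}: " + "  ".join(f"t={t:>2.0f}m {phase[t]:.3f}" for t in samples if t in phase.index))
    print(f"{'':>13}  final G_max fold = {gmax.iloc[-1]:.3f}")
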