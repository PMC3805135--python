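"""The dopamine-enabled activity-dependence rule for I_h G_max.

Calibrates the curve from its two printed anchors and prints the target
G_max fold across burst-duration changes and spike modes.  Key readings:
-30% burst change -> 0.94; with +10% frequency -> 0.87; silence (-100%)
-> the top asymptote (G_max increases); a lumped spike mimic pins the
fold at 1.0; without dopamine the rule is inert.
"""
import pyloop as pl

curve = pl.calibrate_curve("micromolar")
print(f"calibrated: x_half = {curve.x_half:.1f}%, frequency factor = "
      f"{curve.freq_factor_per_10pct:.4f} per +10%\n")

print("delta burst (%)   target fold")
for db in (-100, -60, -30, 0, 30):
    print(f"{db:>13}   {pl.target_fold(pl.ActivityIndex(db), curve):>10.3f}")

print("\nwith +10% cycle frequency at -30%:",
      round(pl.target_fold(pl.ActivityIndex(-30.0, 10.0), curve), 3))
print("same but lumped spike mimic:      ",
      pl.target_fold(pl.ActivityIndex(-30.0, 10.0, spike_mode="lumped"), curve))
print("no dopamine, any activity:        ",
      pl.target_fold(pl.ActivityIndex(-30.0, 10.0), pl.calibrate_curve("none")))

# relaxation kinetics: 10 minutes at tau = 3 min vs patterned spiking (x10)
for mode in ("none", "patterned"):
    state = pl.MetaplasticState(g0=0.1, g=0.1)
    state = pl.advance_gmax(state, pl.ActivityIndex(-30.0, 10.0, spike_mode=mode), curve, dt=10.0)
    print(f"G_max fold after 10 min, spike_mode={mode:<9}: {state.fold:.3f}")
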