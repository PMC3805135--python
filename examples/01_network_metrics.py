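"""Generate paired PD/LP spike trains and recover the dopamine folds.

Builds two minutes of synthetic pyloric activity at baseline and under the
sustained 5 uM dopamine condition, runs burst detection and per-cycle
metrics, and prints the condition folds.  Expected: cycle period ~0.90,
LP-on phase ~0.80, LP burst duration ~0.70, within-burst ISI ~0.66 — the
dopamine signature the metrics pipeline is built to measure.
"""
import pyloop as pl

baseline = pl.baseline_preset(cycle_jitter_sd=20.0, spike_jitter_sd=2.0)
dopamine = pl.apply_da_preset(baseline, pl.da_preset())


def condition_means(preset, seed):
    pd_train, lp_train = pl.generate_network_recording(preset, duration=120000.0, seed=seed)
    per_cycle = pl.cycle_metrics(
        pl.detect_bursts(pd_train, max_isi=150.0),
        pl.detect_bursts(lp_train, max_isi=3 * preset.lp_mean_isi),
    )
    return pl.windowed_average(per_cycle, n=len(per_cycle.loc[~per_cycle.flagged]))


base = condition_means(baseline, seed=1)
da = condition_means(dopamine, seed=2)

print("metric                baseline    dopamine     fold")
for label, col in [("cycle period (ms)", "a_ms"), ("LP-on phase", "lp_on_phase"),
                   ("LP burst (ms)", "c_ms"), ("mean ISI (ms)", "mean_isi_ms")]:
    print(f"{label:<20} {base[col]:>9.3f} {da[col]:>11.3f} {da[col] / base[col]:>8.3f}")
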