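"""Tuning script for the rebound-neuron baseline fixture.

Scans maximal conductances of the rebound neuron around the committed
defaults and reports, for each candidate, the cyclic-steady-state rebound
latency at baseline, after the dopaminergic I_A reduction (g_A x 0.81 with
the period shortened to 900 ms), and with the metaplastic I_h reduction
added (g_h x 0.8625, the activity-dependence target for the dopamine
condition).  A candidate is acceptable when

* the baseline latency is in the 200-300 ms range (phase ~ 0.2-0.3),
* the I_A reduction alone advances the phase by 15-25%
  (fold = (L1/900)/(L0/1000) in [0.75, 0.85]), and
* the added I_h reduction restores the phase to within 5% of baseline.

The defaults committed in `pyloop.loop.default_rebound_config` were chosen
from this scan.  Design rationale: the escape from the I_A brake is a race
between inactivation decay (tau_inact) and the slowly deactivating I_h
drive near the stall voltage, which makes latency near-log-linear in the
g_A:g_h ratio with gain (1/tau_inact - 1/tau_h)^-1; the I_h time constant
is fast at hyperpolarized voltages so the gate resets to its steady state
during every inhibition, keeping cyclic and single-pulse latencies equal.

Run:  python scripts/tune_network.py
"""
import numpy as np

from pyloop.loop import _run_cycle, default_rebound_config


def cyclic_latency(cfg, g_a, g_h, period, n_settle=15, n=25):
    """Rebound latency in the cyclic steady state (ms)."""
    v = cfg.e_leak
    gates = (float(cfg.ih.m_inf(v)), float(cfg.ia.m_inf(v)), float(cfg.ia.h_inf(v)))
    for _ in range(n_settle):
        v, mh, ma, ha, *_ = _run_cycle(cfg, v, gates, cfg.ih.g_max, cfg.ia.g_max, cfg.pacemaker_period)
        gates = (mh, ma, ha)
    latency = np.nan
    for _ in range(n):
        v, mh, ma, ha, cross, _, _ = _run_cycle(cfg, v, gates, g_h, g_a, period)
        gates = (mh, ma, ha)
        latency = cross * cfg.dt - cfg.inh_duration if cross >= 0 else np.nan
    return latency


def main() -> None:
    base = default_rebound_config()
    print(f"{'g_a':>5} {'g_h':>5} {'L0':>6} {'L_ia':>6} {'L_both':>6} {'adv_fold':>8} {'eq_fold':>7}")
    for g_a in (0.16, 0.20, 0.24, 0.28):
        for g_h in (0.35, 0.45, 0.55, 0.65):
            cfg = default_rebound_config(
                ih=base.ih.scaled(g_h / base.ih.g_max), ia=base.ia.scaled(g_a / base.ia.g_max)
            )
            L0 = cyclic_latency(cfg, g_a, g_h, 1000.0)
            L1 = cyclic_latency(cfg, 0.81 * g_a, g_h, 900.0)
            L2 = cyclic_latency(cfg, 0.81 * g_a, 0.8625 * g_h, 900.0)
            adv = (L1 / 900.0) / (L0 / 1000.0)
            eq = (L2 / 900.0) / (L0 / 1000.0)
            ok = "  <-- acceptable" if (0.75 < adv < 0.85 and 0.95 < eq < 1.05 and 200 < L0 < 300) else ""
            print(f"{g_a:5.2f} {g_h:5.2f} {L0:6.1f} {L1:6.1f} {L2:6.1f} {adv:8.3f} {eq:7.3f}{ok}")


if __name__ == "__main__":
    main()
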