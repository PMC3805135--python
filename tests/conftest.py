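"""Shared fixtures.

The closed-loop experiment runs are session-scoped because several tests
read different aspects of the same simulated experiment (folds, ratios,
trajectories); the experiments themselves are deterministic.
"""
import pytest

import pyloop as pl


@pytest.fixture(scope="session")
def baseline():
    return pl.baseline_preset()


@pytest.fixture(scope="session")
def jittered_baseline():
    return pl.baseline_preset(cycle_jitter_sd=20.0, spike_jitter_sd=2.0)


@pytest.fixture(scope="session")
def da():
    return pl.da_preset()


@pytest.fixture(scope="session")
def clamp_burst_only():
    """Recurring-step emulation: 30% shorter step, unchanged period."""
    cfg = pl.default_clamp_config(spike_mode="none", with_frequency_change=False, measure_times_min=(0.0, 10.0))
    return pl.run_clamp_experiment(cfg)


@pytest.fixture(scope="session")
def clamp_combined():
    """Recurring-step emulation: 30% shorter step + 10% faster cycling."""
    cfg = pl.default_clamp_config(spike_mode="none", with_frequency_change=True)
    return pl.run_clamp_experiment(cfg)


@pytest.fixture(scope="session")
def clamp_lumped():
    """Combined command plus the lumped 6 x 2 ms spike-mimicking step."""
    cfg = pl.default_clamp_config(spike_mode="lumped", measure_times_min=(0.0, 10.0))
    return pl.run_clamp_experiment(cfg)


@pytest.fixture(scope="session")
def clamp_no_da():
    """Same activity change without dopamine: plasticity must be inert."""
    cfg = pl.default_clamp_config(da_mode="none", spike_mode="none", measure_times_min=(0.0, 10.0))
    return pl.run_clamp_experiment(cfg)


@pytest.fixture(scope="session")
def network_da():
    """Rebound neuron through a dopamine event, 60 simulated minutes."""
    cfg = pl.default_rebound_config(da_onset_min=2.0)
    return pl.run_network_experiment(cfg, duration_min=60.0)


@pytest.fixture(scope="session")
def network_addback():
    """Same, with the dynamic-clamp add-back engaged at dopamine + 10 min."""
    cfg = pl.default_rebound_config(da_onset_min=2.0, dynamic_clamp_addback=True)
    return pl.run_network_experiment(cfg, duration_min=60.0)


@pytest.fixture(scope="session")
def network_control():
    """No dopamine event within the run."""
    cfg = pl.default_rebound_config(da_onset_min=1e6)
    return pl.run_network_experiment(cfg, duration_min=15.0)
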