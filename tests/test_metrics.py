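"""Burst detection and cycle metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pyloop as pl
from pyloop.core import MeasurementError, SpikeTrain, ValidationError


class TestDetectBursts:
    def test_isi_threshold_grouping(self):
        tbl = pl.detect_bursts(SpikeTrain([0.0, 10.0, 20.0, 500.0, 510.0]), max_isi=100.0, min_spikes=2)
        assert len(tbl) == 2
        assert list(tbl.n_spikes) == [3, 2]

    def test_min_spikes_filter(self):
        assert len(pl.detect_bursts(SpikeTrain([100.0]), max_isi=50.0, min_spikes=2)) == 0

    def test_empty_input_gives_empty_table(self):
        assert len(pl.detect_bursts(SpikeTrain([]), max_isi=50.0)) == 0

    def test_matches_generator_burst_windows(self, baseline):
        """Zero-jitter synthetic LP bursts are recovered exactly."""
        _, lp = pl.generate_network_recording(baseline, 20000.0, seed=1)
        tbl = pl.detect_bursts(lp, max_isi=3 * baseline.lp_mean_isi)
        assert len(tbl) == 20
        assert np.allclose(tbl.duration, baseline.lp_burst_duration)
        assert np.allclose(tbl.first_spike % 1000.0, baseline.lp_on_delay)


class TestCycleMetrics:
    def test_basic_period_delay_phase(self):
        pd_tbl = pl.BurstTable([800.0, 1800.0], [1000.0, 2000.0], [5, 5])
        lp_tbl = pl.BurstTable([1250.0], [1550.0], [7])
        row = pl.cycle_metrics(pd_tbl, lp_tbl).iloc[0]
        assert row.a_ms == 1000.0 and row.b_ms == 250.0 and row.lp_on_phase == 0.25

    def test_da_preset_phase_fold(self, jittered_baseline, da):
        """Phase fold between baseline and dopamine conditions ~ 0.80."""
        scaled = pl.apply_da_preset(jittered_baseline, da)
        def mean_phase(preset, seed):
            pd_t, lp_t = pl.generate_network_recording(preset, 120000.0, seed)
            cm = pl.cycle_metrics(
                pl.detect_bursts(pd_t, 150.0), pl.detect_bursts(lp_t, 3 * preset.lp_mean_isi)
            )
            return cm["lp_on_phase"].mean()
        fold = mean_phase(scaled, 11) / mean_phase(jittered_baseline, 10)
        assert fold == pytest.approx(0.80, abs=0.02)

    def test_unassignable_lp_is_error(self, baseline):
        """LP spikes with no burst structure cannot be paired with PD cycles."""
        pd_t, lp_t = pl.generate_network_recording(baseline, 20000.0, seed=1)
        rng = np.random.default_rng(0)
        shuffled = SpikeTrain(np.sort(rng.uniform(0, 20000.0, size=40)))
        with pytest.raises(MeasurementError):
            pl.cycle_metrics(pl.detect_bursts(pd_t, 150.0), pl.detect_bursts(shuffled, 150.0, min_spikes=2))

    def test_phase_invariant_under_time_rescaling(self, baseline):
        """Phase b/a is dimensionless: rescaling both trains leaves it unchanged."""
        pd_t, lp_t = pl.generate_network_recording(baseline, 20000.0, seed=4)
        cm1 = pl.cycle_metrics(pl.detect_bursts(pd_t, 150.0), pl.detect_bursts(lp_t, 150.0))
        k = 3.7
        cm2 = pl.cycle_metrics(
            pl.detect_bursts(SpikeTrain(pd_t.times_ms * k), 150.0 * k),
            pl.detect_bursts(SpikeTrain(lp_t.times_ms * k), 150.0 * k),
        )
        assert np.allclose(cm1["lp_on_phase"], cm2["lp_on_phase"])


class TestWindowedAverage:
    def test_identical_cycles_average_to_themselves(self, baseline):
        pd_t, lp_t = pl.generate_network_recording(baseline, 20000.0, seed=1)
        cm = pl.cycle_metrics(pl.detect_bursts(pd_t, 150.0), pl.detect_bursts(lp_t, 150.0))
        avg = pl.windowed_average(cm, n=10)
        assert avg["a_ms"] == pytest.approx(1000.0)
        assert avg["lp_on_phase"] == pytest.approx(0.25)

    def test_split_window_mean(self):
        frame = pd.DataFrame({"a_ms": [900.0] * 5 + [1100.0] * 5, "flagged": False})
        for col in pl.metrics.METRIC_COLUMNS:
            if col not in frame.columns:
                frame[col] = 1.0
        assert pl.windowed_average(frame, n=10)["a_ms"] == pytest.approx(1000.0)

    def test_too_few_cycles_rejected(self, baseline):
        pd_t, lp_t = pl.generate_network_recording(baseline, 20000.0, seed=1)
        cm = pl.cycle_metrics(pl.detect_bursts(pd_t, 150.0), pl.detect_bursts(lp_t, 150.0))
        with pytest.raises(ValidationError):
            pl.windowed_average(cm, n=100)


class TestFoldChange:
    def test_constant_series_all_ones(self):
        s = pd.Series([0.25, 0.25, 0.25], index=[0, 10, 20])
        assert (pl.fold_change(s, 0) == 1.0).all()

    @given(ref=st.floats(min_value=0.05, max_value=2.0), scale=st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, ref, scale):
        s = pd.Series([ref, ref * scale, ref * 0.5], index=[0, 10, 20])
        once = pl.fold_change(s, 0)
        assert np.allclose(pl.fold_change(once, 0), once)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            pl.fold_change(pd.Series([0.0, 1.0], index=[0, 10]), 0)

    def test_documented_folds(self):
        s = pd.Series([0.25, 0.20], index=[0, 10])
        assert pl.fold_change(s, 0).loc[10] == pytest.approx(0.80)
        s2 = pd.Series([1000.0, 900.0], index=[0, 10])
        assert pl.fold_change(s2, 0).loc[10] == pytest.approx(0.90)
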