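"""Burst segmentation and cyclic activity metrics.

The conventions mirror standard pyloric-network analysis: the cycle period
``a`` is the time between the last spike of one PD burst and the last spike
of the next; the LP-on delay ``b`` is the time from the last PD spike to the
first LP spike of that cycle; LP-on phase is b/a; LP burst duration ``c`` is
first-to-last LP spike.  Reported summary values are 10-cycle averages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MeasurementError, SpikeTrain, ValidationError

__all__ = [
    "BurstTable",
    "detect_bursts",
    "cycle_metrics",
    "windowed_average",
    "fold_change",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

#: per-cycle metric columns, in reporting order
METRIC_COLUMNS = [
    "a_ms",
    "b_ms",
    "c_ms",
    "lp_off_delay_ms",
    "lp_on_phase",
    "lp_off_phase",
    "mean_isi_ms",
    "spikes_per_burst",
]


@dataclass
class BurstTable:
    """Non-overlapping, ordered bursts of one cell."""

    first_spike: np.ndarray  # ms
    last_spike: np.ndarray  # ms
    n_spikes: np.ndarray  # count

    def __post_init__(self) -> None:
        self.first_spike = np.asarray(self.first_spike, dtype=float)
        self.last_spike = np.asarray(self.last_spike, dtype=float)
        self.n_spikes = np.asarray(self.n_spikes, dtype=int)
        if not (len(self.first_spike) == len(self.last_spike) == len(self.n_spikes)):
            raise ValidationError("BurstTable columns must have equal length")
        if np.any(self.last_spike < self.first_spike):
            raise ValidationError("BurstTable: last_spike must be >= first_spike")
        if len(self.first_spike) > 1 and np.any(self.first_spike[1:] <= self.last_spike[:-1]):
            raise ValidationError("BurstTable: bursts must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.first_spike)

    @property
    def duration(self) -> np.ndarray:
        return self.last_spike - self.first_spike

    @property
    def mean_isi(self) -> np.ndarray:
        """Mean within-burst ISI = (last - first)/(n - 1); NaN for 1-spike bursts."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n_spikes > 1, self.duration / np.maximum(self.n_spikes - 1, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"first_spike_ms": self.first_spike, "last_spike_ms": self.last_spike, "n_spikes": self.n_spikes}
        )


def detect_bursts(train: SpikeTrain, max_isi: float, min_spikes: int = 2) -> BurstTable:
    """Group spikes separated by <= ``max_isi`` into bursts.

    Groups with fewer than ``min_spikes`` spikes are discarded.  The input
    must be sorted (SpikeTrain enforces this); an empty train yields an
    empty table.
    """
    if max_isi <= 0:
        raise ValidationError("max_isi must be > 0")
    t = train.times_ms
    if len(t) == 0:
        return BurstTable(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    breaks = np.flatnonzero(np.diff(t) > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t) - 1]])
    n = ends - starts + 1
    keep = n >= min_spikes
    return BurstTable(t[starts[keep]], t[ends[keep]], n[keep])


def cycle_metrics(pd_bursts: BurstTable, lp_bursts: BurstTable) -> pd.DataFrame:
    """Per-cycle metrics from paired PD and LP burst tables.

    Cycle i spans (last_PD_spike(i), last_PD_spike(i+1)]; an LP burst is
    assigned to cycle i if its first spike falls in that half-open interval.
    Cycles lacking an assignable LP burst are flagged (``flagged`` column),
    not silently dropped.  If more than half of the cycles lack an LP burst
    the inputs are considered mis-paired and an error is raised.
    """
    if len(pd_bursts) < 2:
        raise ValidationError("need >= 2 PD bursts to define a cycle")
    pd_last = pd_bursts.last_spike
    rows = []
    n_flagged = 0
    for i in range(len(pd_last) - 1):
        t0, t1 = pd_last[i], pd_last[i + 1]
        a = t1 - t0
        sel = np.flatnonzero((lp_bursts.first_spike > t0) & (lp_bursts.first_spike <= t1))
        if len(sel) == 0:
            n_flagged += 1
            rows.append({"cycle_start_ms": t0, "a_ms": a, "flagged": True})
            continue
        j = sel[0]  # first LP burst of the cycle defines LP-on
        b = lp_bursts.first_spike[j] - t0
        c = lp_bursts.last_spike[j] - lp_bursts.first_spike[j]
        off = lp_bursts.last_spike[j] - t0
        rows.append(
            {
                "cycle_start_ms": t0,
                "a_ms": a,
                "b_ms": b,
                "c_ms": c,
                "lp_off_delay_ms": off,
                "lp_on_phase": b / a,
                "lp_off_phase": off / a,
                "mean_isi_ms": float(lp_bursts.mean_isi[j]),
                "spikes_per_burst": int(lp_bursts.n_spikes[j]),
                "flagged": False,
            }
        )
    n_cycles = len(pd_last) - 1
    if n_flagged > 0.5 * n_cycles:
        raise MeasurementError(
            f"{n_flagged}/{n_cycles} cycles lack an assignable LP burst; PD/LP inputs look mis-paired"
        )
    if n_flagged:
        logger.info("cycle_metrics: %d/%d cycles lack an LP burst (flagged)", n_flagged, n_cycles)
    frame = pd.DataFrame(rows)
    for col in METRIC_COLUMNS + ["flagged"]:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[["cycle_start_ms"] + METRIC_COLUMNS + ["flagged"]]


def windowed_average(metrics: pd.DataFrame, n: int = 10, start: int = 0) -> pd.Series:
    """Arithmetic mean of each metric over ``n`` consecutive unflagged cycles.

    Flagged (missing-LP) cycles are excluded before windowing, with a logged
    count.  Raises if fewer than ``n`` usable cycles remain.
    """
    if n < 1:
        raise ValidationError("window length n must be >= 1")
    usable = metrics.loc[~metrics["flagged"].astype(bool)]
    n_dropped = len(metrics) - len(usable)
    if n_dropped:
        logger.info("windowed_average: excluded %d flagged cycles", n_dropped)
    if len(usable) - start < n:
        raise ValidationError(f"need >= {n} unflagged cycles from position {start}, have {len(usable) - start}")
    window = usable.iloc[start : start + n]
    return window[METRIC_COLUMNS].mean()


def fold_change(series: pd.Series, reference_time) -> pd.Series:
    """Normalise a metric time course by its value at ``reference_time``.

    ``series`` is indexed by time; the reference is the exact index entry.
    Idempotent: fold_change(fold_change(x, t), t) == fold_change(x, t).
    """
    if reference_time not in series.index:
        raise ValidationError(f"reference_time {reference_time!r} not in series index")
    ref = series.loc[reference_time]
    if ref == 0 or not np.isfinite(ref):
        raise ValidationError("reference value must be non-zero and finite")
    return series / ref
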