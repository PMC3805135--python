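"""Shared containers: uniformly sampled traces, spike trains, seed substreams.

All times are milliseconds, voltages millivolts, currents nanoamperes and
conductances microsiemens unless a unit suffix says otherwise.  Inward
currents are negative by convention.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ValidationError",
    "MeasurementError",
    "SampledTrace",
    "SpikeTrain",
    "substream",
]


class ValidationError(ValueError):
    """A config, preset or input violates a documented invariant."""


class MeasurementError(RuntimeError):
    """A measurement step (fit, detection, simulation read-out) failed."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one top-level seed.

    Every source of randomness in the package draws from a substream so that
    a single integer seed fixes the whole pipeline.  The substream key is a
    CRC32 of ``name``, which keeps distinct module streams independent.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass
class SampledTrace:
    """A uniformly sampled time series (membrane voltage or clamp current).

    Parameters
    ----------
    values : ndarray
        Sample values, one per time step.
    dt_ms : float
        Sampling interval in ms (0.05 ms = 20 kHz is the package default).
    units : str
        Physical units of ``values`` ("mV" or "nA").
    kind : str
        "voltage" or "current".
    t0_ms : float
        Time of the first sample.
    """

    values: np.ndarray
    dt_ms: float
    units: str
    kind: str
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("SampledTrace.values must be 1-D")
        if self.dt_ms <= 0:
            raise ValidationError("SampledTrace.dt_ms must be > 0")
        if self.kind not in ("voltage", "current"):
            raise ValidationError(f"SampledTrace.kind must be voltage|current, got {self.kind!r}")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_ms(self) -> float:
        return len(self) * self.dt_ms

    def time_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self)) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample at (or straddling) absolute time ``t_ms``."""
        i = int(round((t_ms - self.t0_ms) / self.dt_ms))
        if not 0 <= i <= len(self):
            raise ValidationError(f"time {t_ms} ms outside trace [{self.t0_ms}, {self.t0_ms + self.duration_ms}] ms")
        return i

    def window(self, t_start_ms: float, t_end_ms: float) -> "SampledTrace":
        i0, i1 = self.index_at(t_start_ms), self.index_at(t_end_ms)
        return replace(self, values=self.values[i0:i1], t0_ms=self.t0_ms + i0 * self.dt_ms)


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) for one cell."""

    times_ms: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.ndim != 1:
            raise ValidationError("SpikeTrain.times_ms must be 1-D")
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValidationError(f"SpikeTrain {self.cell_id!r}: spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_ms)
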