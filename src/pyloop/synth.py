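"""Synthetic pyloric data with the statistical structure the analysis assumes.

Generates (i) paired pacemaker (PD) and follower (LP) bursting spike trains
with configurable cycle period, burst durations, on-delay, within-burst ISI
and Gaussian jitter; (ii) recurring clamp command waveforms that mimic slow
wave activity, optionally carrying lumped or patterned spike mimics; and
(iii) noisy voltage-clamp current traces forward-simulated from known
channel models plus ohmic leak.

Spike trains are generated directly as spike times, not via a membrane
simulation: the burst/phase metrics operate on spike times, exactly as the
experimental metrics are derived from extracellular records.  The dopamine
condition is a multiplicative rescaling of the baseline preset
(`apply_da_preset`) representing the established, sustained effect of a
5 uM bath application: 10% shorter cycle period, 30% shorter LP bursts,
20% phase advance, ISI reduced to 66%.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .channels import AChannelParams, HChannelParams, channel_current_series, steady_state
from .core import SampledTrace, SpikeTrain, ValidationError, substream
from .tevc import StepProtocol

__all__ = [
    "NetworkPreset",
    "DAPreset",
    "CommandWaveform",
    "baseline_preset",
    "da_preset",
    "apply_da_preset",
    "generate_network_recording",
    "generate_command",
    "generate_clamp_trace",
    "ClampEpisode",
]

DEFAULT_DT_MS = 0.05  # 20 kHz digitization


@dataclass(frozen=True)
class NetworkPreset:
    """Timing parameters of one network condition (all times in ms).

    ``lp_spikes_per_burst`` and ``lp_mean_isi`` are nominal values: spike
    placement spans ``lp_burst_duration`` exactly, with the within-burst ISI
    count drawn by stochastic rounding of duration/mean-ISI so that measured
    burst-duration and mean-ISI ratios independently track their preset
    factors (see docs/methods.md).
    """

    cycle_period: float = 1000.0
    pd_burst_duration: float = 200.0
    lp_burst_duration: float = 300.0
    lp_on_delay: float = 250.0
    lp_spikes_per_burst: int = 6
    lp_mean_isi: float = 50.0
    spike_jitter_sd: float = 0.0
    cycle_jitter_sd: float = 0.0
    pd_spikes_per_burst: int = 5

    def validate(self) -> "NetworkPreset":
        for name in ("cycle_period", "pd_burst_duration", "lp_burst_duration", "lp_on_delay", "lp_mean_isi"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"NetworkPreset.{name} must be > 0")
        for name in ("spike_jitter_sd", "cycle_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"NetworkPreset.{name} must be >= 0")
        if self.lp_spikes_per_burst < 2 or self.pd_spikes_per_burst < 2:
            raise ValidationError("NetworkPreset.lp_spikes_per_burst and pd_spikes_per_burst must be >= 2")
        if not self.lp_on_delay + self.lp_burst_duration < self.cycle_period:
            raise ValidationError("NetworkPreset.lp_on_delay + lp_burst_duration must be < cycle_period")
        if self.lp_mean_isi * (self.lp_spikes_per_burst - 1) > self.lp_burst_duration:
            raise ValidationError("NetworkPreset.lp_mean_isi x (lp_spikes_per_burst - 1) must be <= lp_burst_duration")
        return self

    @property
    def lp_on_phase(self) -> float:
        return self.lp_on_delay / self.cycle_period


@dataclass(frozen=True)
class DAPreset:
    """Multiplicative factors of the sustained 5 uM dopamine condition."""

    period_factor: float = 0.90
    lp_burst_factor: float = 0.70
    lp_on_phase_factor: float = 0.80
    isi_factor: float = 0.66
    ia_gmax_factor: float = 0.81

    def validate(self) -> "DAPreset":
        for name in ("period_factor", "lp_burst_factor", "lp_on_phase_factor", "isi_factor", "ia_gmax_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"DAPreset.{name} must be > 0")
        return self


@dataclass(frozen=True)
class CommandWaveform:
    """A recurring voltage step mimicking slow-wave (and optionally spike)
    activity: the nadir/peak levels, step duration and cycle period mirror
    the average LP oscillation; spike mimics are +40 mV depolarizations of
    2 ms, either lumped into one step of width count x 2 ms or patterned
    with an inter-depolarization gap."""

    nadir_voltage: float = -60.0  # mV
    peak_voltage: float = -40.0  # mV
    step_duration: float = 300.0  # ms
    cycle_period: float = 1000.0  # ms
    spike_mode: str = "none"  # none | lumped | patterned
    spike_peak: float = 40.0  # mV
    spike_width: float = 2.0  # ms
    spike_count: int = 6
    spike_isi: float = 50.0  # ms, gap between patterned depolarizations
    n_cycles: int = 10

    def validate(self) -> "CommandWaveform":
        if self.nadir_voltage >= self.peak_voltage:
            raise ValidationError("CommandWaveform.nadir_voltage must be < peak_voltage")
        if not 0 < self.step_duration < self.cycle_period:
            raise ValidationError("CommandWaveform.step_duration must be in (0, cycle_period)")
        if self.spike_mode not in ("none", "lumped", "patterned"):
            raise ValidationError(f"CommandWaveform.spike_mode must be none|lumped|patterned, got {self.spike_mode!r}")
        if self.spike_mode != "none":
            if self.spike_count < 1 or self.spike_width <= 0:
                raise ValidationError("CommandWaveform spike_count >= 1 and spike_width > 0 required")
            span = self.spike_span
            if span > self.step_duration:
                raise ValidationError(
                    f"CommandWaveform: spike mimic span {span} ms does not fit within step_duration {self.step_duration} ms"
                )
        if self.n_cycles < 1:
            raise ValidationError("CommandWaveform.n_cycles must be >= 1")
        return self

    @property
    def spike_span(self) -> float:
        if self.spike_mode == "lumped":
            return self.spike_count * self.spike_width
        if self.spike_mode == "patterned":
            return self.spike_count * self.spike_width + (self.spike_count - 1) * self.spike_isi
        return 0.0


def baseline_preset(**overrides) -> NetworkPreset:
    """Default baseline network condition (order-of-magnitude fixture:
    1 s period, 300 ms LP burst, phase 0.25, 50 ms ISI)."""
    return replace(NetworkPreset(), **overrides).validate()


def da_preset(**overrides) -> DAPreset:
    return replace(DAPreset(), **overrides).validate()


def apply_da_preset(base: NetworkPreset, da: DAPreset) -> NetworkPreset:
    """Rescale a baseline preset by the dopamine factors.

    period x= period_factor; LP burst x= lp_burst_factor; the on-delay is
    set so that the new phase equals the base phase times
    lp_on_phase_factor; ISI x= isi_factor.
    """
    base.validate()
    da.validate()
    new_period = base.cycle_period * da.period_factor
    out = replace(
        base,
        cycle_period=new_period,
        lp_burst_duration=base.lp_burst_duration * da.lp_burst_factor,
        lp_on_delay=base.lp_on_phase * da.lp_on_phase_factor * new_period,
        lp_mean_isi=base.lp_mean_isi * da.isi_factor,
    )
    return out.validate()


def _jitter(times: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return times
    jittered = np.sort(times + rng.normal(0.0, sd, size=times.shape))
    # enforce strict ordering after the perturbation
    eps = 1e-6
    for i in range(1, len(jittered)):
        if jittered[i] <= jittered[i - 1]:
            jittered[i] = jittered[i - 1] + eps
    return jittered


def _lp_burst_spikes(onset: float, duration: float, mean_isi: float, rng: np.random.Generator) -> np.ndarray:
    """Spikes spanning [onset, onset + duration] with ~duration/mean_isi ISIs.

    The ISI count is the stochastic rounding of duration/mean_isi, so the
    expected total ISI count matches the nominal mean ISI while the first
    and last spikes pin the burst duration exactly.
    """
    x = duration / mean_isi
    k = int(np.floor(x))
    if rng.random() < x - k:
        k += 1
    k = max(1, k)
    return onset + duration * np.arange(k + 1) / k


def generate_network_recording(preset: NetworkPreset, duration: float, seed: int):
    """Paired PD/LP spike trains over ``duration`` ms (>= 10 cycles).

    Cycle anchors sit at k x period plus independent Gaussian onset jitter;
    each PD burst ends at its cycle anchor (so the anchor is the "last PD
    spike" that defines cycle period), and the LP burst starts lp_on_delay
    later.  Per-spike Gaussian jitter is applied afterwards, truncated to
    preserve ordering.
    """
    preset.validate()
    if duration < 10 * preset.cycle_period:
        raise ValidationError("duration must be >= 10 x cycle_period")
    rng = substream(seed, "network")
    n_cycles = int(np.floor(duration / preset.cycle_period))
    anchors = np.arange(1, n_cycles + 1) * preset.cycle_period
    if preset.cycle_jitter_sd > 0:
        anchors = anchors + rng.normal(0.0, preset.cycle_jitter_sd, size=anchors.shape)

    pd_spikes = []
    lp_spikes = []
    n_pd = preset.pd_spikes_per_burst
    for a in anchors:
        pd_spikes.append(a - preset.pd_burst_duration * (n_pd - 1 - np.arange(n_pd)) / (n_pd - 1))
        lp_spikes.append(_lp_burst_spikes(a + preset.lp_on_delay, preset.lp_burst_duration, preset.lp_mean_isi, rng))
    pd_times = _jitter(np.concatenate(pd_spikes), preset.spike_jitter_sd, rng)
    lp_times = _jitter(np.concatenate(lp_spikes), preset.spike_jitter_sd, rng)
    return SpikeTrain(pd_times, "PD"), SpikeTrain(lp_times, "LP")


def generate_command(waveform: CommandWaveform, dt: float = DEFAULT_DT_MS) -> SampledTrace:
    """Render a recurring-step command waveform as a sampled voltage trace.

    Each cycle holds the nadir voltage, steps to the peak voltage for
    ``step_duration`` starting at the cycle onset, and carries the spike
    mimic (if any) at the start of the depolarized step.
    """
    waveform.validate()
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    n_per_cycle = int(round(waveform.cycle_period / dt))
    n_step = int(round(waveform.step_duration / dt))
    cycle = np.full(n_per_cycle, waveform.nadir_voltage)
    cycle[:n_step] = waveform.peak_voltage
    if waveform.spike_mode == "lumped":
        cycle[: int(round(waveform.spike_count * waveform.spike_width / dt))] = waveform.spike_peak
    elif waveform.spike_mode == "patterned":
        w = int(round(waveform.spike_width / dt))
        stride = int(round((waveform.spike_width + waveform.spike_isi) / dt))
        for k in range(waveform.spike_count):
            cycle[k * stride : k * stride + w] = waveform.spike_peak
    return SampledTrace(np.tile(cycle, waveform.n_cycles), dt, "mV", "voltage")


@dataclass
class ClampEpisode:
    """One protocol step rendered as command voltage + summed model current."""

    command: SampledTrace
    current: SampledTrace
    prepulse_level: float
    test_level: float
    test_start_ms: float
    test_end_ms: float

    @property
    def step_window(self) -> tuple[float, float]:
        return (self.test_start_ms, self.test_end_ms)


def _render_step(protocol: StepProtocol, step, dt: float, pad_ms: float):
    pre_level, pre_ms, test_level, test_ms = step
    n_pad = int(round(pad_ms / dt))
    n_pre = int(round(pre_ms / dt))
    n_test = int(round(test_ms / dt))
    v = np.concatenate(
        [
            np.full(n_pad, protocol.holding),
            np.full(n_pre, pre_level),
            np.full(n_test, test_level),
        ]
    )
    t_test = (n_pad + n_pre) * dt
    return SampledTrace(v, dt, "mV", "voltage"), t_test, t_test + n_test * dt


def generate_clamp_trace(
    channels: list,
    leak: tuple[float, float],
    protocol: StepProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = DEFAULT_DT_MS,
    pad_ms: float = 100.0,
) -> list[ClampEpisode]:
    """Forward-simulate a TEVC protocol: one noisy current trace per step.

    Each episode is the sum of the ohmic leak ``g_leak * (V - E_leak)`` and
    every channel's forward-Euler model current under the commanded voltage,
    plus additive zero-mean white Gaussian noise.  Gates start at their
    steady state at the holding potential (the 6 s inter-step interval at
    holding is long enough to relax them, so it is not rendered beyond a
    short pad).

    Parameters
    ----------
    channels : list of HChannelParams | AChannelParams
        May be empty (pure leak).
    leak : (g_uS, e_mV)
    """
    protocol_steps = protocol.steps
    g_leak, e_leak = leak
    rng = substream(seed, "clamp-noise")
    episodes = []
    for step in protocol_steps:
        command, t0, t1 = _render_step(protocol, step, dt, pad_ms)
        current = g_leak * (command.values - e_leak)
        for params in channels:
            state0 = steady_state(params, protocol.holding)
            current = current + channel_current_series(command, params, state0)
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=current.shape)
        episodes.append(
            ClampEpisode(
                command=command,
                current=SampledTrace(current, dt, "nA", "current"),
                prepulse_level=step[0],
                test_level=step[2],
                test_start_ms=t0,
                test_end_ms=t1,
            )
        )
    return episodes
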