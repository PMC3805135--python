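"""Two-electrode voltage-clamp (TEVC) measurement chain.

Protocols, exponential back-extrapolation of the slowly developing I_h,
prepulse leak subtraction for the transient I_A, current-to-conductance
conversion and first-order Boltzmann activation fits.

Sign conventions: inward currents are negative.  I_h elicited by
hyperpolarizing steps is inward (negative); peak I_A at +60 mV is outward
(positive).  For a current activated by hyperpolarization the fitted
Boltzmann slope is positive, for activation by depolarization it is
negative (conventions reported in the fit object).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import MeasurementError, SampledTrace, ValidationError

__all__ = [
    "StepProtocol",
    "ExpFit",
    "BoltzmannFit",
    "ih_protocol",
    "ia_test_protocol",
    "ia_leak_protocol",
    "measure_ih_peak",
    "measure_ia_peak",
    "to_conductance",
    "fit_boltzmann",
]


@dataclass(frozen=True)
class StepProtocol:
    """A family of prepulse/test voltage steps from a common holding level.

    Each entry of ``steps`` is (prepulse_level_mV, prepulse_ms,
    test_level_mV, test_ms); ``inter_step_ms`` is the settling time at
    holding between consecutive steps.
    """

    holding: float  # mV
    steps: tuple  # of (prepulse_level, prepulse_ms, test_level, test_ms)
    inter_step: float = 6000.0  # ms

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("StepProtocol.steps must be non-empty")
        for s in self.steps:
            if len(s) != 4:
                raise ValidationError("each step is (prepulse_mV, prepulse_ms, test_mV, test_ms)")
            if s[1] < 0 or s[3] <= 0:
                raise ValidationError("step durations must be > 0")
        if self.inter_step < 0:
            raise ValidationError("inter_step must be >= 0")


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential fit I(t) = offset + amplitude * (1 - exp(-t/tau))."""

    amplitude: float  # nA, slowly developing component extrapolated to step onset
    tau: float  # ms
    offset: float  # nA, instantaneous (leak) current at step onset
    rmse: float  # nA

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("ExpFit.tau must be > 0")


@dataclass(frozen=True)
class BoltzmannFit:
    """First-order Boltzmann fit G(V) = gmax / (1 + exp((V - v_half)/v_slope))."""

    gmax: float  # uS
    v_half: float  # mV
    v_slope: float  # mV; >0 means activation by hyperpolarization
    rmse: float  # uS

    def __post_init__(self) -> None:
        if self.gmax <= 0:
            raise ValidationError("BoltzmannFit.gmax must be > 0")
        if self.v_slope == 0:
            raise ValidationError("BoltzmannFit.v_slope must be non-zero")

    def __call__(self, v):
        return self.gmax / (1.0 + np.exp((np.asarray(v, dtype=float) - self.v_half) / self.v_slope))


def ih_protocol() -> StepProtocol:
    """The I_h activation protocol: from a -50 mV holding potential, a series
    of seven 4 s hyperpolarizing steps from -60 to -120 mV in 10 mV
    increments, 6 s apart."""
    steps = tuple((-50.0, 500.0, float(v), 4000.0) for v in range(-60, -130, -10))
    return StepProtocol(holding=-50.0, steps=steps, inter_step=6000.0)


def ia_test_protocol() -> StepProtocol:
    """The I_A test protocol: 200 ms deinactivating prepulse to -90 mV,
    then a 400 ms activation pulse to +60 mV."""
    return StepProtocol(holding=-50.0, steps=((-90.0, 200.0, 60.0, 400.0),), inter_step=6000.0)


def ia_leak_protocol() -> StepProtocol:
    """The I_A leak protocol: identical timing but with the prepulse at
    -40 mV, which leaves resting inactivation in place so the test step
    carries only leak (plus any residual non-A current)."""
    return StepProtocol(holding=-50.0, steps=((-40.0, 200.0, 60.0, 400.0),), inter_step=6000.0)


def _window_indices(trace: SampledTrace, step_window) -> tuple[int, int]:
    t0, t1 = step_window
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 <= i0:
        raise ValidationError("empty step window")
    return i0, i1


def measure_ih_peak(
    trace: SampledTrace,
    step_window,
    method: str = "exp_fit",
    skip_ms: float = 5.0,
    rmse_max_nA: float | None = None,
):
    """Steady-state I_h developed during a hyperpolarizing step.

    Parameters
    ----------
    trace : SampledTrace
        Clamp current trace containing the test step.
    step_window : (t_start_ms, t_end_ms)
        Absolute times bounding the test step within the trace.
    method : {"exp_fit", "peak_minus_leak"}
        ``exp_fit`` fits a single exponential to the slowly developing
        current (excluding the first ``skip_ms`` after the step, which holds
        the capacitive/fast-leak transient) and back-extrapolates to the
        step onset; the exponential amplitude is the steady-state I_h with
        leak excluded.  ``peak_minus_leak`` subtracts the initial fast leak
        current (mean over 2-10 ms post-step) from the late current (mean
        over the final 10% of the step) — the fallback used when
        oscillations interrupt the trace and prevent curve fitting.
    rmse_max_nA : float, optional
        If given and the exponential fit's residual RMSE exceeds it, a
        MeasurementError recommending ``peak_minus_leak`` is raised.

    Returns
    -------
    (steady_state_current_nA, ExpFit or None)
        Sign preserved: inward currents are negative.
    """
    i0, i1 = _window_indices(trace, step_window)
    y = trace.values[i0:i1]
    t = np.arange(i1 - i0) * trace.dt_ms

    early = slice(trace.index_at(step_window[0] + 2.0) - i0, trace.index_at(step_window[0] + 10.0) - i0)
    i_fast = float(np.mean(y[early]))
    late = y[int(0.9 * len(y)) :]
    i_late = float(np.mean(late))

    if method == "peak_minus_leak":
        return i_late - i_fast, None
    if method != "exp_fit":
        raise ValidationError(f"unknown method {method!r}")

    skip = max(1, int(round(skip_ms / trace.dt_ms)))
    tf, yf = t[skip:], y[skip:]

    def model(tt, amp, tau, off):
        return off + amp * (1.0 - np.exp(-tt / tau))

    p0 = (i_late - i_fast, (t[-1] - t[0]) / 5.0, i_fast)
    try:
        popt, _ = curve_fit(
            model,
            tf,
            yf,
            p0=p0,
            bounds=([-np.inf, trace.dt_ms, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise MeasurementError(
            f"exponential fit did not converge (initial guess amp={p0[0]:.3g} nA, "
            f"tau={p0[1]:.3g} ms, offset={p0[2]:.3g} nA); consider method='peak_minus_leak'"
        ) from exc
    amp, tau, off = popt
    rmse = float(np.sqrt(np.mean((model(tf, *popt) - yf) ** 2)))
    if rmse_max_nA is not None and rmse > rmse_max_nA:
        raise MeasurementError(
            f"exponential fit RMSE {rmse:.3g} nA exceeds {rmse_max_nA} nA; consider method='peak_minus_leak'"
        )
    return float(amp), ExpFit(amplitude=float(amp), tau=float(tau), offset=float(off), rmse=rmse)


def measure_ia_peak(
    test_trace: SampledTrace,
    leak_trace: SampledTrace,
    step_window=None,
    smooth_ms: float = 0.5,
) -> float:
    """Peak I_A by prepulse leak subtraction.

    The leak trace (prepulse at -40 mV, no deinactivation) is subtracted
    sample-by-sample from the test trace (-90 mV deinactivating prepulse);
    the peak of the difference current during the +60 mV activation step is
    returned.  A short boxcar (``smooth_ms``) is applied to the difference
    before taking the maximum so that, on noisy traces, the peak is not the
    maximum of the noise.
    """
    if len(test_trace) != len(leak_trace):
        raise ValidationError(f"trace length mismatch: {len(test_trace)} vs {len(leak_trace)}")
    if test_trace.dt_ms != leak_trace.dt_ms:
        raise ValidationError("trace dt mismatch")
    diff = test_trace.values - leak_trace.values
    if step_window is not None:
        i0, i1 = _window_indices(test_trace, step_window)
        diff = diff[i0:i1]
    w = max(1, int(round(smooth_ms / test_trace.dt_ms)))
    if w > 1:
        diff = np.convolve(diff, np.ones(w) / w, mode="valid")
    return float(np.max(diff))


def to_conductance(i_peak: float, v: float, v_rev: float) -> float:
    """Chord conductance G = I_peak / (V_m - V_rev) in uS (nA / mV)."""
    if v == v_rev:
        raise ValidationError("v must differ from v_rev")
    return i_peak / (v - v_rev)


def fit_boltzmann(voltages, conductances, v_slope_guess: float = 8.0) -> BoltzmannFit:
    """Least-squares first-order Boltzmann fit of an activation curve.

    Initialisation: gmax = max |G|; v_half = voltage where G crosses half
    max (linear interpolation); v_slope = ``v_slope_guess`` (+8 mV, the
    hyperpolarization-activated convention; pass a negative guess for
    depolarization-activated data).
    """
    v = np.asarray(voltages, dtype=float)
    g = np.asarray(conductances, dtype=float)
    if len(v) < 4:
        raise ValidationError("need >= 4 points spanning the transition")
    gmax0 = float(np.max(np.abs(g)))
    order = np.argsort(g)  # interp needs ascending x; pairs (G, V) stay matched
    vh0 = float(np.interp(gmax0 / 2.0, g[order], v[order]))

    def model(vv, gmax, v_half, v_slope):
        return gmax / (1.0 + np.exp((vv - v_half) / v_slope))

    p0 = (gmax0, vh0, v_slope_guess)
    try:
        popt, _ = curve_fit(model, v, g, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise MeasurementError(
            f"Boltzmann fit did not converge (initial guess gmax={p0[0]:.3g} uS, "
            f"v_half={p0[1]:.3g} mV, v_slope={p0[2]:.3g} mV)"
        ) from exc
    rmse = float(np.sqrt(np.mean((model(v, *popt) - g) ** 2)))
    gmax, v_half, v_slope = (float(x) for x in popt)
    if gmax <= 0:
        raise MeasurementError(
            f"Boltzmann fit converged to non-physical gmax={gmax:.3g} uS "
            f"(initial guess gmax={p0[0]:.3g}, v_half={p0[1]:.3g}, v_slope={p0[2]:.3g})"
        )
    return BoltzmannFit(gmax=gmax, v_half=v_half, v_slope=v_slope, rmse=rmse)
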