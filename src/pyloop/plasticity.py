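"""Dopamine-enabled activity-dependent regulation of I_h G_max.

Dopamine does not modulate I_h directly; it *enables* activity to regulate
it.  The rule has four ingredients:

1. An activity-dependence curve: the target fold-change of G_max is a
   descending Boltzmann sigmoid over the percent change in burst duration
   relative to baseline.  -100% means silence (activity fully blocked), at
   which the target is the curve's top asymptote (G_max increases); at the
   dopamine-typical -30% burst change the target is 0.94 (a ~6% reduction).
2. A multiplicative cycle-frequency factor: a +10% cycle-frequency change
   multiplies the target by 0.87/0.94 ~= 0.926, calibrated from the ratio of
   the two anchored folds (0.94 with burst change only, 0.87 with the
   frequency increase added).
3. Spike gating: a lumped spike-mimicking depolarization abolishes the
   effect entirely (target pinned at 1.0); patterned spike activity slows it
   (relaxation time constant multiplied by ``patterned_tau_multiplier``).
4. Concentration modes: "micromolar" and "nanomolar" dopamine both enable
   the rule (the nanomolar curve is anchored so that unchanged activity
   leaves G_max unchanged); mode "none" disables plasticity entirely —
   without dopamine, activity alone does nothing.

G_max relaxes first-order toward its activity-determined target; the update
uses the exact exponential step, so it is unconditionally stable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core import ValidationError

__all__ = [
    "ActivityIndex",
    "ADCurveParams",
    "MetaplasticState",
    "calibrate_curve",
    "target_fold",
    "advance_gmax",
]

#: printed anchor folds of the activity-dependence calibration
ANCHOR_BURST_PCT = -30.0
ANCHOR_FOLD_BURST_ONLY = 0.94
ANCHOR_FOLD_WITH_FREQ = 0.87
ANCHOR_FREQ_PCT = 10.0


@dataclass(frozen=True)
class ActivityIndex:
    """Activity relative to the pre-dopamine baseline (10-cycle averages)."""

    delta_burst_pct: float  # % change in burst duration; -100 = silent
    delta_freq_pct: float = 0.0  # % change in cycle frequency
    spike_mode: str = "none"  # none | lumped | patterned

    def __post_init__(self) -> None:
        if self.delta_burst_pct < -100.0:
            raise ValidationError("delta_burst_pct cannot be below -100 (silence)")
        if self.spike_mode not in ("none", "lumped", "patterned"):
            raise ValidationError(f"spike_mode must be none|lumped|patterned, got {self.spike_mode!r}")


@dataclass(frozen=True)
class ADCurveParams:
    """Calibrated activity-dependence curve.

    fold(x) = bottom + (top - bottom) / (1 + exp((x - x_half)/x_slope))
    over x = delta_burst_pct, times freq_factor_per_10pct**(delta_freq/10).
    ``top`` (G_max fold under silence) and ``x_slope`` are assumptions (the
    corresponding observations are figure-only); x_half is solved from the
    printed anchor, and the frequency factor from the ratio of the two
    printed anchors.
    """

    top: float  # fold at x -> -inf (silence asymptote)
    bottom: float  # fold at x -> +inf
    x_half: float  # % burst change at half transition
    x_slope: float  # % (positive: fold decreases with burst change)
    freq_factor_per_10pct: float
    da_mode: str  # micromolar | nanomolar | none
    tau_ad: float = 3.0  # minutes
    patterned_tau_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if not self.top > self.bottom > 0:
            raise ValidationError("ADCurveParams requires top > bottom > 0")
        if self.tau_ad <= 0:
            raise ValidationError("ADCurveParams.tau_ad must be > 0")
        if self.freq_factor_per_10pct <= 0:
            raise ValidationError("ADCurveParams.freq_factor_per_10pct must be > 0")
        if self.x_slope <= 0:
            raise ValidationError("ADCurveParams.x_slope must be > 0")
        if self.da_mode not in ("micromolar", "nanomolar", "none"):
            raise ValidationError(f"da_mode must be micromolar|nanomolar|none, got {self.da_mode!r}")

    def burst_fold(self, delta_burst_pct: float) -> float:
        return self.bottom + (self.top - self.bottom) / (1.0 + math.exp((delta_burst_pct - self.x_half) / self.x_slope))


@dataclass
class MetaplasticState:
    """Current I_h G_max under the activity-dependent rule."""

    g0: float  # uS, pre-dopamine G_max
    g: float  # uS, current G_max
    target_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.g0 <= 0 or self.g <= 0:
            raise ValidationError("MetaplasticState conductances must be > 0")

    @property
    def fold(self) -> float:
        return self.g / self.g0


def _solve_x_half(anchor_x: float, anchor_fold: float, top: float, bottom: float, x_slope: float) -> float:
    span = top - bottom
    if not bottom < anchor_fold < top:
        raise ValidationError(
            f"anchor fold {anchor_fold} not bracketed by (bottom={bottom}, top={top}); "
            "no monotone Boltzmann passes through it"
        )
    r = span / (anchor_fold - bottom) - 1.0
    return anchor_x - x_slope * math.log(r)


def calibrate_curve(
    da_mode: str = "micromolar",
    top: float = 1.10,
    bottom: float = 0.70,
    x_slope: float = 20.0,
    tau_ad: float = 3.0,
    patterned_tau_multiplier: float = 10.0,
) -> ADCurveParams:
    """Calibrate the activity-dependence curve from the printed anchors.

    micromolar: the curve passes through (-30% burst change, fold 0.94);
    the frequency factor is the ratio 0.87/0.94 of the two anchored folds.
    nanomolar: the curve is pinned so unchanged activity gives fold 1.0
    (no change in G_max when slow-wave activity is merely mimicked).
    none: no dopamine — the rule is inert (fold identically 1.0).
    """
    freq_factor = ANCHOR_FOLD_WITH_FREQ / ANCHOR_FOLD_BURST_ONLY
    if da_mode == "micromolar":
        x_half = _solve_x_half(ANCHOR_BURST_PCT, ANCHOR_FOLD_BURST_ONLY, top, bottom, x_slope)
    elif da_mode == "nanomolar":
        x_half = _solve_x_half(0.0, 1.0, top, bottom, x_slope)
    elif da_mode == "none":
        x_half = 0.0
    else:
        raise ValidationError(f"da_mode must be micromolar|nanomolar|none, got {da_mode!r}")
    return ADCurveParams(
        top=top,
        bottom=bottom,
        x_half=x_half,
        x_slope=x_slope,
        freq_factor_per_10pct=freq_factor,
        da_mode=da_mode,
        tau_ad=tau_ad,
        patterned_tau_multiplier=patterned_tau_multiplier,
    )


def target_fold(index: ActivityIndex, curve: ADCurveParams) -> float:
    """Activity-determined target fold of I_h G_max.

    No dopamine -> 1.0 regardless of activity.  A lumped spike mimic fully
    gates the rule (1.0).  Otherwise the burst-duration Boltzmann times the
    frequency factor raised to (delta_freq/10), saturated at the curve's
    asymptotes: the top/bottom folds bound what the mechanism can express,
    so the combined target is clamped into [bottom, top].
    """
    if curve.da_mode == "none":
        return 1.0
    if index.spike_mode == "lumped":
        return 1.0
    fold = curve.burst_fold(index.delta_burst_pct) * curve.freq_factor_per_10pct ** (index.delta_freq_pct / 10.0)
    return min(curve.top, max(curve.bottom, fold))


def advance_gmax(state: MetaplasticState, index: ActivityIndex, curve: ADCurveParams, dt: float) -> MetaplasticState:
    """Relax G_max toward its activity-determined target over ``dt`` minutes.

    Exact exponential update g <- target + (g - target) exp(-dt/tau), with
    tau = tau_ad (times patterned_tau_multiplier under patterned spiking),
    so the step is unconditionally stable for any dt.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0 minutes")
    fold = target_fold(index, curve)
    tau = curve.tau_ad * (curve.patterned_tau_multiplier if index.spike_mode == "patterned" else 1.0)
    target = fold * state.g0
    g = target + (state.g - target) * math.exp(-dt / tau)
    return MetaplasticState(g0=state.g0, g=g, target_fold=fold)
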