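# Methods

`pyloop` models a closed feedback loop through which a neuromodulator
simultaneously perturbs and stabilises a rhythmic motor circuit.  The
biological system is the pyloric central pattern generator of the crustacean
stomatogastric ganglion: a pacemaker kernel (AB/PD) rhythmically inhibits
follower neurons, and each follower's firing phase is set by its rate of
post-inhibitory rebound, which in turn is governed by the ratio of two
opposing subthreshold conductances — the transient potassium current I_A
(outward, delays rebound) and the hyperpolarization-activated current I_h
(inward, accelerates it).  Micromolar dopamine acts on low-affinity D1
receptors of the LP follower to reduce I_A, advancing the LP phase and
shortening its burst; it simultaneously acts on high-affinity D1 receptors to
*enable* activity-dependent regulation of I_h, so the altered activity then
drives I_h down until the I_A:I_h ratio — and the phase — is restored.

The package implements the full measurement and modelling chain on synthetic
data: generators, burst/phase metrics, a voltage-clamp analysis pipeline,
conductance models with a dynamic-clamp engine, the calibrated
activity-dependence rule, and two closed-loop experiment emulations.

## Synthetic data

Spike trains are generated directly as spike times (no membrane simulation):
the metrics operate on spike times exactly as the experimental metrics are
derived from extracellular records.  The baseline condition is a fixture of
realistic order of magnitude: cycle period 1000 ms, LP-on delay 250 ms (phase
0.25), LP burst 300 ms, mean within-burst ISI 50 ms, PD burst 200 ms.  The
dopamine condition is a multiplicative rescaling: period x 0.90, LP burst
x 0.70, LP-on phase x 0.80, ISI x 0.66, plus the direct I_A conductance
factor 0.81.  Jitter is independent Gaussian noise on cycle onsets and on
individual spikes, truncated to preserve ordering; the defaults used in the
acceptance runs are 20 ms (cycle) and 2 ms (spike).

One structural choice deserves note.  Mean within-burst ISI is identically
(burst duration)/(ISI count), so burst-duration and ISI folds of 0.70 and
0.66 with a *fixed* spike count are arithmetically impossible; the
experimental reports are only compatible if spikes per burst drifts slightly
(a ~6% change, well inside "no significant change").  The generator therefore
spans the burst duration exactly and draws the ISI count by stochastic
rounding of duration/mean-ISI, so both folds are recovered simultaneously
and the expected spike count tracks the nominal values.

Clamp-current traces are forward-simulated from the channel models under the
protocol's command voltage, plus ohmic leak and additive white Gaussian noise
(default 0.05 nA where noise is wanted).  No drift or oscillation artifacts
are modelled.

## Channel models and integration

I_h uses the dynamic-clamp form: I = G_max * m * (V - E_rev) with
E_rev = -35 mV, first-order Boltzmann steady state
m_inf = 1/(1 + exp((V - V_half)/V_slope)) and dm/dt = (m_inf - m)/tau_m(V),
integrated by fixed-step forward Euler at dt = 0.05 ms (20 kHz).  Defaults
V_half = -95 mV, V_slope = +8 mV and a bell-shaped tau_m peaking at 800 ms
are assumptions chosen so the current reaches steady state within the 4 s
protocol steps; they are fixtures, not measured values.  I_A uses the classic
m^3 h scheme (activation -30/-10 mV, tau 10 ms; inactivation -60/+6 mV, tau
80 ms; E_K = -80 mV assumed), also a fixture — the underlying Kv4 kinetics
are not published for this preparation.  Gates are clamped to [0, 1] after
every step; for constant voltage the Euler trajectory matches the closed-form
exponential within 1% at dt = tau/100 (tested).  The dopaminergic I_A
modulation is implemented as multiplicative G_max scaling (x 0.81) although
the underlying receptor mechanism may act on voltage dependence; the peak
current fold is the measured quantity either way.

## Voltage-clamp analysis

The I_h protocol holds at -50 mV and applies seven 4 s steps from -60 to
-120 mV in 10 mV increments, 6 s apart.  Steady-state I_h is the amplitude of
a single exponential fitted to the developing current and back-extrapolated
to the step onset; the first 5 ms after the step are excluded (capacitive
transient).  When fitting fails or its residual exceeds a caller-set bound, a
`peak_minus_leak` fallback subtracts the initial fast current (mean over
2-10 ms post-step) from the late current (mean over the final 10% of the
step).  Conductance is the chord G = I/(V - E_rev); the activation curve is a
least-squares first-order Boltzmann initialised at gmax = max|G|, V_half at
the interpolated half-max, V_slope = 8 mV.  Positive fitted slope denotes
activation by hyperpolarization.

Peak I_A is measured at +60 mV (400 ms) after a 200 ms deinactivating
prepulse to -90 mV, minus the trace recorded with a -40 mV prepulse (leak
path, channels kept inactivated); a 0.5 ms boxcar is applied to the
difference before taking the maximum so that on noisy traces the peak is not
the maximum of the noise.  I_A is reported as peak current, not conductance.

## The activity-dependence rule

The target fold of I_h G_max is a descending Boltzmann sigmoid over the
percent change in burst duration relative to the pre-dopamine baseline
(computed from 10-cycle averages), times a cycle-frequency factor:

    F(db, df) = clamp[ bottom + (top - bottom)/(1 + exp((db - x_half)/x_slope)) ]
                * f10^(df/10),   clamped into [bottom, top]

Two quantitative anchors calibrate it: F(-30, 0) = 0.94 and
F(-30, +10) = 0.87, giving f10 = 0.87/0.94 = 0.9255.  The asymptotes
(top = 1.10, the G_max increase under silence; bottom = 0.70) and the slope
(x_slope = 20%) are read only qualitatively from the source experiments and
are therefore assumptions; x_half is solved from the anchor.  The nanomolar
mode pins F(0, 0) = 1 instead (unchanged activity leaves G_max unchanged at
tonic dopamine); mode "none" disables the rule entirely — without dopamine,
activity alone does nothing, which is the central gating claim.  The clamp
into [bottom, top] also bounds the combined burst-and-frequency target, so
the G_max trajectory can never leave [g0*bottom, g0*top].

Spike gating: a lumped spike-mimicking depolarization (one +40 mV step of
spikes-per-burst x 2 ms) abolishes the rule (target pinned at 1.0); patterned
spikes (2 ms depolarizations separated by 0.66 x the baseline ISI) slow it by
multiplying the relaxation time constant by `patterned_tau_multiplier`
(default 10).  G_max relaxes toward its target as an exact exponential with
tau_ad = 3 min by default: the experiments show full expression by 10 min but
no kinetics, and 3 min puts 10 min at ~96% completion.  A consequence worth
stating: measured at exactly 10 min, the burst-only reduction is 5.79%, not
the asymptotic 6%.

Whether burst-duration and frequency dependences are truly separable and
multiplicative is not established by the source data; the factorised form is
the simplest rule consistent with both anchors.

## Closed-loop clamp emulation

`run_clamp_experiment` reproduces the repeated-measurement protocols: a
recurring command waveform (slow-wave mimic) sets the activity index relative
to a baseline command — burst change from the step-duration ratio, frequency
change from the period ratio, spike mode from the waveform — while peak I_h,
I_h G_max (full Boltzmann over the seven-step I-V) and peak I_A are
re-measured through the complete in-silico clamp chain at each measurement
time (default 0, 10, 30, 60 min).  The I_A factor 0.81 is applied at dopamine
onset in micromolar mode.  The command mimicking the dopamine condition uses
a 30% shorter step and a period divided by 1.1 (the frequency change is
stated as "+10%" for these protocols).  With both changes, peak I_h settles
at 0.870 of baseline and the I_A:I_h ratio at 0.931 — each current changed
by >= 13% (asymptotically) while the ratio stayed within 10% of unity.

## Rebound-neuron network experiment

`run_network_experiment` composes everything into a minimal circuit: a
single-compartment neuron (C = 2 nF) with leak (0.02 uS, -43 mV), I_A and
I_h, driven by a periodic square inhibitory conductance pulse (1 uS to
-80 mV, 500 ms of each 1000 ms cycle) standing in for the pacemaker burst.
Spiking is a threshold proxy at -45 mV: burst onset is the first
suprathreshold crossing after inhibition ends, burst duration the
suprathreshold time.  Channel dynamics advance at 0.05 ms; the metaplastic
G_max updates once per cycle (its minutes-scale tau makes finer updating
irrelevant).  The activity index uses the running 10-cycle mean burst
duration against the 10-cycle pre-dopamine reference; spike mode is
"patterned" because the neuron is spiking (unlike the TTX-silenced clamp
protocols), which slows the rule tenfold and reproduces the observed
separation of time scales: the ratio restores within ~10 min in clamp
emulations, the phase recovers over tens of minutes in the network.

The baseline conductances (g_A = 0.20 uS, g_h = 0.55 uS) are a tuned fixture
(`scripts/tune_network.py` is the scan that selected them).  The neuron's
channel variants (I_A activation -50/-8 mV, inactivation -75/+5 mV with
tau_inact = 220 ms; I_h tau bell centred at -45 mV, width 8 mV) place the
rebound in a regime where escape from the I_A brake is a race between
inactivation decay and the slowly deactivating I_h drive near the stall
voltage.  Latency is then near-log-linear in the g_A:g_h ratio with gain
(1/tau_inact - 1/tau_h)^-1, which is what lets a 19% g_A reduction advance
the phase by ~18-20% and a subsequent ~14% g_h reduction restore it.  The
I_h time constant is deliberately fast at hyperpolarized voltages so the
gate resets to its steady state during every inhibition: cyclic and
single-pulse latencies then agree, and the limit cycle is insensitive to
history.  A dopamine event scales g_A by 0.81 and the pacemaker period by
0.90 (the inhibitory pulse duration is unchanged — pacemaker burst duration
is not modelled as period-dependent).  The dynamic-clamp add-back cancels
the instantaneous metaplastic change (effective g_h pinned at its
pre-dopamine value) from 10 min after dopamine onset, and holds the phase
advanced indefinitely.

Emergent numbers from the committed fixture: phase fold 0.82 at dopamine
onset, 0.90 at +10 min, recovery to within 2.5% of baseline at steady state
with G_max settling near 0.87 of baseline and burst duration near 0.70 —
self-consistent with the calibration anchors, which is the closed loop
working as designed rather than a coincidence.

## What the synthetic data do and do not show

The generators emulate the *statistical shape* of the recordings (burst
timing, jitter, clamp noise) and the folds that define the dopamine
condition; they do not emulate electrode artifacts, space-clamp error,
residual TTX oscillations, graded synaptic transmission, calcium dynamics or
the D1R signalling cascade.  Passing tests therefore demonstrate that the
measurement chain recovers known ground truth and that the model's feedback
structure produces the documented phenomenology; they are not evidence about
biological kinetics beyond the anchored values.

## Numerical choices and degenerate inputs

Forward Euler everywhere, fixed dt = 0.05 ms (gate updates clamp to [0, 1];
steps larger than the local tau log a warning).  The metaplastic update is an
exact exponential, unconditionally stable for any step.  Exponential and
Boltzmann fits use `scipy.optimize.curve_fit` with the documented
initialisations and raise `MeasurementError` (reporting the initial guess,
and recommending `peak_minus_leak` where applicable) on non-convergence.
Burst detection requires sorted input and returns an empty table for an empty
train; cycle pairing flags (rather than drops) cycles lacking an LP burst and
errors when more than half are unpaired.  `rebound_latency` errors if no
threshold crossing occurs within one pacemaker period, and the network
experiment errors with parameter diagnostics if the neuron falls silent.
Problem sizes were chosen at desk scale: 10-minute recordings (~600 cycles)
for metric recovery, 60 simulated minutes for the network runs.

## Known limitations

- All channel kinetics beyond the anchored folds are fixtures; absolute
  conductance values are arbitrary scale.
- The rebound neuron has no sodium spikes, no calcium currents, no synaptic
  depression, and a one-way pacemaker (no LP-to-pacemaker feedback), so it
  demonstrates the loop's logic, not pyloric biophysics.
- The activity-dependence rule is phenomenological; no calcium-sensor
  mechanism is modelled.
- LP-off phase is computed but unweighted: its biological counterpart is
  confounded by a synaptic pathway outside this model's scope.
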