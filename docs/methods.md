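# Methods

This note documents the model implemented by `shiftstim`, the calibrated
constants it relies on, the numerical choices, and what the synthetic
experiments can and cannot show.

## Neuron and network model

Membrane potentials are dimensionless (threshold-normalized) leaky
integrate-and-fire units:

    dv_i/dλ = −v_i + I_syn + I_ext + I_stim,     λ = t / τ_m

with τ_m = 10 ms, threshold v_th = 1, reset v_r = 0, integrated by forward
Euler at dt = 0.1 ms. A neuron that crosses threshold emits a spike, resets,
and is clamped at reset for an absolute refractory period τ_ref = 2 ms
(stimulation kicks arriving during refractoriness are ignored). The
refractory period is part of the neuron model here: without any rate bound
the strongly coupled two-module system diverges to one spike per
integration step, a regime with no scientific content.

Each presynaptic neuron carries an exponential trace s_j with τ_s = 5 ms
that jumps by 1 at each spike; the synaptic current onto neuron *i* sums
±g_ij·s_j over presynaptic partners, negative for inhibitory cells.
Intra-module transmission is instantaneous; inter-module currents use the
trace delayed by the total conduction delay τ = τ_d + τ_a (0.5 + 10.5 =
11 ms by default). Delays are integer multiples of dt and implemented as
ring buffers.

**Architecture.** Two modules of N = 200 neurons (160 excitatory, 40
inhibitory), Erdős–Rényi connectivity at p = 0.15 within and between
modules, no self-connections. Intra-module weights are static Gaussian
draws (inhibitory mean 0.8, excitatory mean 0.2, sd 0.05, clipped into
[g_min, g_max] = [0.05, 1]); summed inhibition therefore matches summed
local excitation (local balance). Inter-module synapses exist only between
excitatory cells, are drawn per direction independently (default mean 0.8
— the "pathologically strong" preset; a weak preset with mean 0.2 is
provided), and are the only plastic synapses.

**Long-range current scale.** Plastic weights g ∈ [0.05, 1] live on the
scale on which the STDP amplitudes, the weight bounds and the stability
threshold are defined. A single calibrated constant converts them into
currents: I = `inter_current_scale` · g · s, with the default chosen per
expected in-degree (0.6 / (p·N_ex) = 0.025 at the reference size, which
keeps the summed long-range current per neuron invariant under
down-scaling). The constant was calibrated — before any plasticity
experiments — so that the three dynamical regimes the model is built
around exist: an isolated or decoupled module fires asynchronously and
irregularly at a few Hz; the strongly coupled pair (mean 0.8) fires at a
pathologically elevated ~26–29 Hz, below the 33.3 Hz stimulation
frequency so that stimulation pulses preempt spontaneous spikes; and
couplings below roughly half the weight range no longer sustain the
elevated state. The two-neuron motif sets the scale to 1 (a single
synapse is not a population projection).

**Background drive.** Every excitatory neuron receives 8000 independent
1 Hz Poisson trains, every inhibitory neuron 6500; superposition makes
this one aggregate Poisson process per neuron (8000 / 6500 Hz). Each
arrival adds a calibrated amplitude to an external trace: w_ext = 0.0225
for excitatory cells and 0.0315 for inhibitory cells. The per-class split
is a calibration necessity: with a single amplitude the inhibitory
population (fewer input trains) engages too late and the module jumps
from silence straight into a mean-driven high-rate state; with the
calibrated pair the isolated module sits in the fluctuation-driven,
inhibition-stabilized regime (excitatory rate ≈ 8 Hz, CV of inter-spike
intervals ≈ 0.9, low population Fano factor). `calibrate_drive` ships the
scan that produced these numbers. The motif uses w_ext = 0.021 so its two
neurons fire stochastically at a low rate and the stimulation pattern,
not spontaneous coincidences, governs plasticity.

## Plasticity

Inter-module synapses follow a pair-based additive STDP rule evaluated at
**synapse-local arrival times**: a presynaptic somatic spike at t reaches
the synapse at t + τ_a, a postsynaptic spike back-propagates to it at
t + τ_d, so the synapse sees the lag Δ = (t_post − t_pre) + ξ with
ξ = τ_d − τ_a (negative for long-range links, |ξ| = 10 ms by default).
Each arrival pairs with the partner's most recent arrival (nearest-spike
pairing, updates at both pre- and post-arrival events):

    Δg = A₊ · e^(−Δ/τ₊)   if Δ > 0
    Δg = −A₋ · e^(Δ/τ₋)   if Δ < 0,    no change at Δ = 0

with A₊ = 0.008, A₋ = 0.005, τ₊ = 10 ms, τ₋ = 20 ms (depression-dominated
in the integral sense: A₊τ₊ < A₋τ₋). Updates are additive with hard
clipping to [0.05, 1]. Pairing at arrival times rather than pairing
somatic spikes and shifting afterwards matters whenever |ξ| is large
enough to reorder events at the synapse; only the arrival-time scheme
makes the online rule consistent with the period-averaged theory below,
and the equivalence is enforced by test.

## Period-averaged theory

For two neurons firing periodically (period T, somatic lag Δt) each
synapse receives exactly one potentiation and one depression event per
period. With y = (Δt + ξ) mod T reduced into [0, T):

    Δg(T) = A₊·e^(−y/τ₊) − A₋·e^(−(T−y)/τ₋).

The sign pair over the two directions of a reciprocal connection
classifies the (Δt, T) plane into decoupled / unidirectional /
bidirectional regimes. Conventions: lags are reduced modulo T before
evaluation (lags outside one period are rejected, callers reduce first);
a net change of exactly zero defers to the other direction's sign, or
falls back to "unidirectional" when both vanish, keeping the
classification deterministic on the measure-zero boundary; the y = 0
boundary itself takes the closed form's zero-lag limit (full
potentiation), while the event rule's sgn(0) = 0 gives no update there —
the two definitions differ only on that null set. Grid resolution
defaults to 1 ms per axis.

## Stimulation protocol

Two pulse signals target the two modules. Signal 1 starts at t_start,
signal 2 at t_start + Δt; within a burst, pulses repeat every T (ν = 1/T);
after the k-th pulse the gap is T_OFF. Defaults: T = 30 ms (33.3 Hz),
k = 5 (ON epoch (k−1)·T = 120 ms), T_OFF = 360 ms, T_stim = 5 s per
signal, onset 10 s. The continuous pattern sets T_OFF = T. Pulses
strictly after onset + T_stim are dropped (half-open window). Each pulse
adds K = 1.3 (30 % above threshold) to the membrane of every targeted
neuron instantaneously, so a non-refractory neuron fires within one
step; targets are all / excitatory-only / inhibitory-only per module.
K is a model choice (no reference value exists); note that a
suprathreshold kick makes coincident (Δt = 0) control pulses produce
exactly zero somatic lags, which the sign function maps to no update.

## Analysis

All before/after comparisons use 10 s windows by default (2 s at reduced
scale); the window is recorded in every report. Defaults: population
activity in 1 ms bins (5 ms moving average for peak and phase detection),
spike-count correlations in 50 ms bins over all pairs up to 200 neurons
(seeded subsample beyond), population Fano factor on 5 ms-binned
activity, spectral peak as the argmax of the mean-subtracted magnitude
spectrum in 1–100 Hz, phase lags by peak matching against the median
cycle of module 1. The inter-population mean coupling is reported
per-edge (mean plastic synaptic strength — the scale of the weight
bounds and of the ~0.3 stability threshold) by default; the per-neuron
normalization (summed strength / module size), which grows with
connection density, is exposed as an option. Thresholded binary topology
keeps links with g ≥ h (default h = 0.3).

## Problem sizes

The acceptance script simulates the reference conditions: two modules of
200 neurons, stimulation onset at 10 s, 5 s of stimulation, 10 s
post-offset analysis, 25 s of simulated time at dt = 0.1 ms (a few
minutes on one CPU). The test suite runs most simulation tests on
proportionally shrunk networks (20–100 neurons per module, 1–7 s of
simulated time); the per-in-degree current scale keeps per-neuron
long-range input comparable across sizes, and the reduced runs preserve
the sign of the headline effects. Two acceptance tests run at the full
module size.

## What the synthetic experiments show — and what they do not

The network generator *is* the experiment definition: Erdős–Rényi
connectivity, Gaussian weights, homogeneous Poisson drive, two identical
modules. Passing tests therefore demonstrate the internal consistency of
the model — the analytic map predicts the sign of stimulation-induced
weight change in the spiking network, the time-shifted protocol weakens
the inter-population coupling and its effect persists after offset —
under exactly these idealized conditions. They do not show robustness to
heterogeneous cell properties, structured or distance-dependent
connectivity, conductance-based synapses, short-term plasticity, or
plastic local circuits, none of which are modelled.

Two quantitative caveats are inherent to the event-based reading of the
pair rule and are documented because they bound what the simulations can
reproduce:

1. **Magnitude of the 5 s effect.** One pairing event changes a weight by
   at most A₋ = 0.005, and the burst protocol contains ~55 pulse periods,
   so the mean coupling cannot drop by more than ~0.28 during a single
   5 s epoch even in the fully entrained ideal — and the theoretical
   per-period changes at the reference stimulation point are
   (−0.0032, −0.0006). Starting from strong coupling (0.8), a single
   epoch suppresses the coupling by a few hundredths to ~0.1; driving it
   below the ~0.3 stability threshold requires repeated epochs or larger
   plasticity amplitudes. The package reports what the model actually
   produces.

2. **The coincident control.** With suprathreshold pulses, a Δt = 0
   control produces exactly coincident forced spikes, whose zero lag the
   sign function maps to no update; any net drift of the control then
   comes from spontaneous activity. Under the printed rule the
   direction-averaged per-period change at Δt = 0 with |ξ| = 10 ms
   equals that at Δt = 5 ms, so the shifted/unshifted contrast at this
   delay is carried by network effects, not by the rule itself.

## Known limitations

- Forward Euler with spike detection at step boundaries quantizes spike
  times to dt; the event-driven plasticity path is dt-invariant for
  forced spike trains (tested), while the free-running network dynamics
  are chaotic and only statistically reproducible across dt.
- The two modules are statistically identical; asymmetric module sizes or
  drives are representable in the types but not exercised by the shipped
  experiments.
- No closed-loop (activity-triggered) stimulation; schedules are fixed at
  construction.
- Phase-lag extraction assumes a detectable collective rhythm and raises
  otherwise; in weakly synchronized states the distribution is noisy.
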