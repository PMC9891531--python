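# shiftstim

Tools for studying how a **time shift between periodic stimulus trains
delivered to two reciprocally connected neuronal populations** reshapes the
synapses between them through spike-timing-dependent plasticity (STDP), and
whether that reshaping desynchronizes the populations in a way that outlasts
the stimulation.

The package is aimed at computational neuroscientists exploring
multichannel, temporally patterned brain-stimulation protocols: it provides
an analytic theory for choosing the stimulation frequency and time shift, a
spiking-network simulator to test the prediction in a two-module cortical
network model, the stimulation-protocol generator, and the synchrony metrics
used to judge the outcome.

## The model

**Pair-based STDP with transmission delays.** A synapse from presynaptic
neuron *j* to postsynaptic neuron *i* changes on each nearest spike pairing
by

```
Δg = A± · sgn(Δt + ξ) · exp(−|Δt + ξ| / τ±)
```

where Δt = t_post − t_pre is the somatic spike lag, ξ = τ_d − τ_a is the
*effective delay* at the synapse (dendritic back-propagation minus axonal
conduction; negative for long-range projections), A₊/τ₊ apply when the
synapse-local lag is positive (potentiation) and A₋/τ₋ when negative
(depression). Updates are additive with hard bounds g ∈ [0.05, 1].

**Period-averaged theory.** If the two neurons fire periodically with period
T and lag Δt, each synapse accumulates one potentiation and one depression
event per period; with y = (Δt + ξ) mod T the net change per period is

```
Δg(T) = A₊ · exp(−y/τ₊) − A₋ · exp(−(T − y)/τ₋).
```

Evaluating the sign of Δg(T) for both directions of a reciprocal pair
partitions the (Δt, T) plane into **decoupled** (both synapses decay),
**bidirectional** (both grow) and **unidirectional** regimes — the map that
tells you which stimulation frequency ν = 1/T and time shift Δt will
*unlearn* a pathologically strong reciprocal coupling.

**Two-module network.** Each module is a sparse random network of 200
leaky integrate-and-fire neurons (160 excitatory, 40 inhibitory; inhibitory
synapses 4-fold stronger on average), driven by aggregate Poisson input and
operating in an inhibition-stabilized, asynchronous-irregular regime when
isolated. The modules interact only through delayed, plastic
excitatory-to-excitatory projections (total delay 11 ms); when that coupling
is strong the pair synchronizes at an elevated rate — the "pathological"
state the stimulation is designed to dissolve.

## Worked example

The analytic map, evaluated at the two reference stimulation points:

```python
>>> from shiftstim import STDPParams, net_change, classify_pair
>>> stdp = STDPParams()            # A+ = 0.008, A- = 0.005, tau+ = 10, tau- = 20
>>> net_change(15.0, 30.0, stdp, xi=0.0)      # anti-phase, no delay
-0.0005767914825176349
>>> classify_pair(15.0, 30.0, stdp, xi=0.0)
<RegionLabel.DECOUPLED: 'decoupled'>
>>> xi = 0.5 - 10.5                            # |xi| = 10 ms long-range delay
>>> net_change(5.0, 30.0, stdp, xi), net_change(25.0, 30.0, stdp, xi)
(-0.003237323926365834, -0.0005767914825176349)
>>> classify_pair(21.0, 45.0, stdp, xi)        # spontaneous firing point
<RegionLabel.BIDIRECTIONAL: 'bidirectional'>
```

Both per-period changes at (Δt, T) = (5, 30) ms with |ξ| = 10 ms are
negative: a 33.3 Hz protocol with a 5 ms shift should depress the coupling
in both directions, while the spontaneous near-anti-phase firing at
(21, 45) ms potentiates it — the pathological state is self-sustaining
until stimulated.

The same prediction tested on the two-neuron motif (stochastically firing
pair, reciprocal plastic synapses, 5 s of time-shifted bursts):

```python
>>> from shiftstim.experiments import decoupling_run
>>> out = decoupling_run("reduced", seed=3, motif=True, overrides={
...     "pre": 1000.0, "stim": 5000.0, "post": 500.0, "window": 500.0,
...     "delta_t": 5.0, "g_init": 0.5})
>>> r = out["result"]
>>> float(r.g21_series[20]), float(r.g21_series[-1])   # onset -> end
(0.5, 0.3186165037142183)
>>> float(r.g12_series[20]), float(r.g12_series[-1])
(0.49999999998399813, 0.45207042921084684)
```

Both synapses are weaker after stimulation, the forward one strongly so —
the sign and asymmetry the theory predicts at that stimulation point.

A command-line interface exposes the same pipeline
(`shiftstim theory-map`, `simulate`, `sweep`, `check-module`,
`report-topology`); try
`shiftstim theory-map --T 10:100:1 --dt 0:100:1 --xi 10 --out map.csv`.

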