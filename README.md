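# spikefx

A fixed-point, multiplier-less, event-driven spiking neural network
simulator with an embedded three-factor learning engine — a software
model of the class of digital neuromorphic cores that compute with
16-bit states, 8-bit synapses, power-of-two coefficients and
address-event spike routing, aimed at researchers prototyping embedded
on-line learning algorithms before committing them to hardware.

## The model

Neurons are multi-compartment linear units advanced by a per-tick
difference equation in pure integer arithmetic:

```
x[t+1] = sat( x[t] + A ◇ x[t] + (Ξ[t] ∘ W) · s[t] + η[t] + b )
if x0[t+1] ≥ θ0:  spike, reset, refractory clamp
```

where every entry of the transition matrix `A` is a signed power of two
applied with a *corrected* bit shift `◇` (truncation toward zero, so
`(-2^a') ◇ -a = 0` for `a' < a` — a plain arithmetic shift would leave
small negative states stuck at −1), `Ξ` is a per-delivery Bernoulli
blank-out mask (stochastic synapses), `η` keyed integer noise and `W`
the 8-bit weight matrix. Learning is a pre-sensitive, forward-table,
nearest-neighbor STDP rule modulated by a third factor — a designated
state component `x_m` of the post-synaptic neuron:

```
Δw_ij = x_m ◇ ( K[t − t_i] + K[t_j − t] )      (clipped, randomized-rounded)
```

with the kernel `K` a staircase of shift exponents and randomized
rounding making low-precision updates unbiased in expectation. All
randomness is counter-based (keyed by seed, neuron/synapse id and
tick), so simulations are bit-reproducible and independent of how
neurons are partitioned across cores.

Five built-in demonstration models exercise the engine: the
Mihalas-Niebur firing-behavior repertoire, Amari neural-field bump /
action-selection / tracking dynamics, event-driven random
back-propagation (supervised), an event-driven restricted Boltzmann
machine trained with contrastive divergence, and voltage/calcium-based
spike-sequence learning. See `docs/methods.md` for the science and
`examples/` for narrative scripts.

## Worked example

`examples/02_stdp_pair.py` pairs a plastic input with a driven
post-synaptic neuron whose modulator is held at 16, then recomputes the
total weight change with an offline brute-force nearest-neighbor
pairing:

```
$ python examples/02_stdp_pair.py
pre spikes: 30, post spikes: 47
event-driven engine total weight change: 1200
brute-force nearest-neighbor oracle:     1200
```

The two totals are the same integer: in the refractory ≥ window regime
the event-driven forward-table engine *is* nearest-neighbor STDP, not an
approximation of it. Similarly, `examples/03_neural_field_bump.py`
prints

```
stimulus on  [0, 400): inside    279.4  outside    0.0  center  49.8
after removal [400, 2500): inside   1046.0  outside    0.0  center 50.4
```

— the mean spike counts of field units inside/outside the stimulated
range: the activity bump ignited by a 400-tick stimulus persists,
self-sustained by the quantized difference-of-Gaussians coupling, for
the remaining 2100 ticks.

## Command line

A thin CLI wraps the library:

```
spikefx run --config net.yaml --ticks 1000 --seed 7 --out out/
spikefx validate --config net.yaml
spikefx demo mnn --preset tonic
spikefx demo field --preset stationary-bump
spikefx demo erbp|erbm|seqlearn [--epochs N] [--seed S]
```

Outputs are plain text: a `tick,core,neuron` raster CSV, weight
snapshots, optional state traces and a JSON run summary carrying the
seed, a config hash, spike and SynOp counts.

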