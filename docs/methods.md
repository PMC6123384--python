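# Methods

`spikefx` is a behaviorally exact software model of a fixed-point,
multiplier-less, event-driven spiking neural network engine with an
embedded three-factor learning rule. This note records the model, the
numerical conventions, the design decisions taken where the design was
genuinely open, what the synthetic benchmarks do and do not show, and the
known limitations.

## Neuron model

A neuron is a vector of `k` (1–8) signed 16-bit state components
`x = (x_0 … x_{k-1})` advanced once per tick (nominally 1 ms) by the
difference equation

```
x[t+1] = sat( x[t] + A ◇ x[t] + acc[t] + η[t] + b )
```

* `A` is a k×k transition matrix whose entries are **signed powers of
  two** (sign ∈ {−1, 0, +1}, |exponent| ≤ 15), applied with the corrected
  shift described below; component couplings build multi-compartment
  cells (membrane, synaptic currents, calcium traces, adaptive
  thresholds, plasticity modulators).
* `acc` is the synaptic input accumulated during the *previous* tick's
  second stage (32-bit accumulator, saturating), after per-delivery
  Bernoulli blank-out masking and a per-component power-of-two gain.
* `η` is zero-mean integer noise with variance `2^e`, built as the sum of
  four keyed uniform draws (an integer approximation of a normal
  deviate). The realized variance is within 10 % of `2^e` — the nearest
  achievable with integer half-widths.
* `b` is a constant per-component drive; a network-level per-neuron
  `bias_extra` array adds to it (used for clamp currents).
* Saturation is at the word bounds (no wraparound); an optional
  per-component floor (`x_min`) supports non-negative integrators.

Component 0 is the spiking compartment: `x_0 ≥ θ_0` emits a spike
(comparison is `≥`), after which `x_0` is clamped at its reset value for
the refractory period while other components keep evolving. Any
component with reset enabled is independently set to its reset value
when it crosses its own threshold — this per-component conditional reset
is how adaptive thresholds are built. One optional nonlinear element per
group, a comparator (`x_tgt = v_ge if x_src ≥ θ_c else v_lt`), encodes a
membrane-voltage switch; it exists because a step function of one
component cannot be expressed in the linear dynamics, and the
voltage/calcium sequence-learning rule requires exactly that.

## Fixed-point conventions

* **Corrected shift (`shift_mult`)** — `x·2^a` with truncation toward
  zero on down-shifts: `sign(x)·(|x| >> −a)`. The plain arithmetic right
  shift of a two's-complement negative number rounds toward −∞
  (`-4 >> 3 == -1`), which would leave small negative states orbiting
  −1 forever; the corrected shift returns 0 there
  (`shift_mult(-a, -2^{a'}) = 0` for all `a' < a`). Up-shifts saturate.
* **Leak operator (`leak_apply`)** — `sign·shift_mult(exp, x)` with a
  guaranteed one-LSB decay toward zero whenever a negative-signed
  coefficient's shifted magnitude truncates to zero and `x ≠ 0`. The
  rule applies to both polarities of `x`; without it, any state with
  `|x| < 2^{-exp}` would stall and never reach rest. A pure leak
  therefore reaches exactly 0 from any 16-bit initial value, strictly
  decreasing in `|x|`.
* **Randomized rounding** — a weight update `Δ` committed with `r`
  rounding bits becomes `(|Δ| >> r) + Bernoulli(low r bits / 2^r)` with
  the sign re-applied (symmetric magnitude rounding). The expectation is
  exactly `Δ/2^r`, which is what makes 8-bit weights usable for
  gradient-style learning.
* **Counter-based randomness** — every draw (noise, blank-out, rounding,
  synthetic inputs) is a pure function of
  (seed, neuron-or-synapse id, tick, purpose, lane) through a splitmix64
  finalizer chain. No RNG state exists, so runs are reproducible, draws
  can be replayed (the plasticity engine re-derives the blank-out mask a
  delivery used), and results are independent of how neurons are
  assigned to cores. The hardware-style LFSR is deliberately not
  emulated bit-for-bit.

## Two-stage tick loop

Each tick: **stage 1** (all cores) integrates dynamics and detects
threshold crossings; a barrier; **routing** schedules each spike's
fanout at `emission + 1 + axonal delay`; a barrier; **stage 2** (all
cores) accumulates the deliveries due this tick and runs plasticity. A
spike emitted at `t` with zero delay is thus accumulated at `t+1` and
first moves the target's state at `t+2`. External events stamped `t` are
treated as emitted at `t−1` by virtual input neurons, so they obey the
same availability rule. Cores are simulated sequentially between
barriers; because nothing is keyed by core, any partition of neurons
over cores produces a bit-identical raster (verified for 1/2/4 cores).
The run record counts SynOps — deliveries actually accumulated after
blank-out — as the cost metric.

## Three-factor forward-table STDP

All plasticity is pre-sensitive: updates are triggered by pre-synaptic
events or by the expiry of the pre-neuron's timer, touching only forward
rows of the synapse table (no reverse lookups; timer memory is O(N) in
neurons). On a pre spike at `p`: pending causal updates of the previous
pre spike are committed first (earliest post spike in its window), then
each post target whose most recent spike lies within the acausal window
receives an acausal update, then the timer restarts; an undisturbed
timer commits the causal window at `p + T_ca`. Lag-0 coincidences pair
causally (causal wins ties). With refractory ≥ window this is exactly
nearest-neighbor STDP — the acceptance suite checks integer-for-integer
equality with a brute-force offline oracle over 200 random Poisson
pairs.

The kernel is a staircase of shift exponents (exponential mode decrements
the exponent every half-decay step; linear mode uses explicit
breakpoints), zero outside `[−T_ac, T_ca]`. The committed update is the
kernel exponent applied as a bit shift to the post-neuron's **modulator
component** `x_m` — the third factor — optionally gated by a boxcar on
another component, then randomized-rounded into the clipped 8-bit
weight. The default operand order shifts the modulator by the kernel
exponent (update linear in `x_m`), because error-modulated learning
requires linearity in the error signal; the literal reverse order is
retained behind `modulation_mode`. `x_m` is sampled at commit time. A
`state_driven` mode bypasses spike-timing entirely: every pre spike
commits `x_m` (the acausal pipeline alone), which is the form taken by
the eRBP and sequence-learning rules. `update_on_dropped` selects
whether plasticity sees pre-mask spikes (synaptic-sampling mode) or only
delivered ones.

Because nearest pairing needs the *earliest* post spike in a causal
window, each neuron keeps a ring of its last 8 spike ticks rather than a
single timestamp; with refractory ≥ window one entry is ever used. If
more than 8 spikes fall inside one window the oldest is forgotten — an
accepted approximation far outside the exact-equivalence regime.

## Demonstration models

**Firing-behavior battery (`models.mnn`).** A generalized
integrate-and-fire cell with adaptive threshold and after-spike currents
is mapped onto the engine through a difference coordinate: component 0
carries `V − Θ` and spikes at a fixed threshold; threshold adaptation
(integrating depolarization) and after-spike currents (pumped by an
autapse on each spike, with their own decay) occupy the remaining
components. Published continuous constants do not round exactly onto
signed powers of two, so preset parameters are re-derived integers and
the acceptance surface is the qualitative behavior class: tonic (ISI
CV < 0.1), phasic (all spikes in the first quarter), mixed (early ISIs
≤ half the settled ISIs, then regular), tonic bursting (bimodal ISI,
inter/intra ratio ≥ 4; produced by a fast depolarizing plus a slow
hyperpolarizing after-spike current), class I (f-I onset ≤ 20 Hz) and
class II (silent below rheobase, onset ≥ 40 Hz; produced by a
near-threshold reset and a threshold offset of one LSB above the
drive's asymptote). Each classifier rejects at least one other preset.

**Neural fields (`models.field`).** 100 lattice units with
difference-of-Gaussians lateral weights, uniform-quantized
(`Q(r) = Δ·⌊r/Δ + 0.5⌋`, Δ = 1/128 = one 8-bit weight LSB), resets
disabled so a unit above threshold fires every tick — its spike train is
the Heaviside indicator of the field equation, making the recurrent
input reproduce the convolution term tick by tick. Units carry a second
fast compartment that low-passes the sparse external Poisson events into
a current; without it a single shared synaptic gain cannot serve both
the rare, large input events and the every-tick recurrent drive. Presets:
stationary bump (35 Hz on units 40–60 vs 10 Hz background for 400 ticks;
the bump self-sustains through tick 2500), action selection (two 50 Hz
patches, broad inhibition σ_i = 30 forces a single winner; symmetry is
broken by input Poisson fluctuations), tracking (asymmetric kernel,
a 50 Hz patch displaced every 500 ticks; the bump re-centers within 250
ticks, settling ~1 unit ahead of the patch in the direction of the
kernel asymmetry). Kernel amplitudes were chosen by simulation so that
an isolated unit cannot ignite its neighbors (no spontaneous satellite
bumps from the background input) while a contiguous stimulated cluster
is self-sustaining.

**eRBP (`models.erbp`).** Data→hidden→prediction feed-forward network
with stochastic (p = 1/2 blank-out) synapses; per class one regular
label channel (ISI = refractory) and a positive/negative error-neuron
pair implemented as non-leaky integrators with a floor at 0, reset on
threshold — their rate is a rectified, 1/6-scaled version of the
prediction/label rate mismatch (threshold = 6 label-quanta filters the
jitter between the regular label train and the stochastic prediction
train). Error spikes feed the modulator compartment of prediction
neurons one-to-one (signed) and of hidden neurons through a fixed random
zero-sum projection. Plasticity is the state-driven, boxcar-gated,
modulator-valued rule with r = 6 rounding bits; updates are frozen for
the first 60 ticks of each 250-tick presentation. The benchmark is a
synthetic two-class task (16 inputs, a fixed random half of them at
50 Hz per class, 10 hidden, 2 classes, 500 presentations): evaluation
error is non-increasing across checkpoints and final accuracy exceeds
90 % on each of 5 seeds. This scaled task stands in for full-image
classification, which needs an external download and hours of
simulation; `synth.load_idx` supports it but no test depends on it.

**eRBM / eCD (`models.erbm`).** 18 visible units (16 pixels + 2 class
units) and a hidden layer, all-to-all with *shared* weight storage: the
visible→hidden and hidden→visible synapse tables index the same slots,
so W = Wᵀ holds exactly at every tick, and the model is restricted to a
single core. Synapses are stochastic and weight updates apply even for
dropped spikes (synaptic-sampling mode — dropped spikes are still valid
samples). Two modulatory channels alternate: the excitatory one during
the data phase (visible clamped by fixed-point logit currents of the
pixel intensities, clipped away from 0 and 1, plus membrane noise)
drives every unit's modulator positive so symmetric nearest-neighbor
STDP potentiates co-activity; the inhibitory one during the free-running
reconstruction phase drives it negative, depressing co-activity — a
spiking contrastive-divergence estimate. The negative-phase amplitude is
twice the positive one, compensating the measured ~2:1 co-activity
asymmetry between clamped and free phases so weights equilibrate inside
the 8-bit range. Operating point: clamped pixels fire near the
refractory cap; hidden units sit subthreshold with the threshold placed
between the equilibria of partial and full feature drive (in units of
the noise σ), which is what makes their rates feature-selective; class
units form a separate lower-threshold readout group. Classification
clamps only the pixels and takes the argmax of free-running class-unit
activity.

**Sequence learning (`models.seqlearn`).** 100 Poisson inputs to 5
four-component neurons: membrane `V`, calcium trace `Ca` (pumped by an
autapse per output spike), comparator component `Θ_m` (= +8 above the
membrane gate, −2 below), and `mod = Θ_m + η_h(Ca_set − Ca)` recomputed
each tick (η_h < 0 so firing above the calcium set point suppresses
potentiation; the opposite sign is unstable — silence and runaway are
both self-reinforcing). Every input spike commits `mod` verbatim
(state-driven plasticity, weights clipped to [0, 127]). On the
embedded-pattern task (a frozen 50-tick pattern alternating with
matched-rate noise, 200 repeats) the outputs become sparse detectors of
the recurring pattern: the working regime has the neuron firing well
below the input-driven ceiling (θ = 800 ≈ 2× the mean drive), so that
only recurring coincidences — which only the frozen pattern provides —
reach the LTP gate reliably. Calcium must be represented at a scale
where its slow decay exceeds the one-LSB minimum-decay floor (γ·2² per
spike against a 2⁻⁸ leak); at small scales the minimum decay destroys
the trace, which silently disables homeostasis.

## Synthetic inputs

Poisson trains are Bernoulli-per-tick (`p = rate·1 ms`; at the rates
used, ≤ 50 Hz, the bias against exact Poisson is ~2 %), keyed by
(seed, channel, tick) — bit-identical on regeneration. The
bars-and-stripes set is all 16 row-generated and 16 column-generated
4×4 binary patterns with class labels; the all-on and all-off patterns
appear once in each class and are inherently ambiguous (an irreducible
~6 % error floor for 32-pattern evaluation). The embedded-pattern
generator freezes one pattern segment and re-presents it among fresh
noise segments of the same rate, returning ground-truth windows.

## Problem sizes and budgets

All benchmarks are desk-scale by design: the behavior battery uses
1000–2000-tick single-neuron runs; the field battery 2500 ticks × 200
units; STDP-oracle equivalence 200 pairs × 10⁴ ticks in one vectorized
network; eRBP 5 seeds × 500 × 250 ticks; eRBM 5 seeds × 50 epochs × 32
samples with 30-tick phases; sequence learning 200 pattern repeats
(20 050 ticks). These sizes were chosen so the full suite completes in
minutes on a single CPU while every statistical criterion retains a 3σ
or better margin.

## What the synthetic benchmarks do and do not show

The generators emulate the *statistical structure* the algorithms rely
on (rate codes, frozen spatiotemporal patterns, class-conditional rate
masks, exact pattern sets), not real sensor data: no temporal
correlations beyond the frozen patterns, no rate drift, no
class-conditional covariance beyond the mean mask. Passing them shows
the fixed-point engine and learning rules are implemented correctly and
can learn under their intended regimes; it does not show that the
specific integer presets transfer to natural stimuli, and trajectories
are not bit-comparable to any other implementation because the integer
parameter sets are re-derived here.

## Known limitations

* The minimum-decay leak injects a ±1 LSB bias into genuinely
  *coupling* (off-diagonal, negative-signed) terms when the source state
  is small; models avoid configurations where this matters.
* Saturating adds inside one accumulation tick are applied after
  summation (order-independent, hence partition-invariant), which can
  differ from a sequential saturating chain near the accumulator bounds.
* More than 8 post spikes inside one STDP window lose the oldest
  pairing candidate.
* The spiking contrastive-divergence demonstration learns weak features
  at this scale; its classification margin on bars-and-stripes is
  sensitive to the sampling operating point (see the module docstring),
  unlike the other four demonstrations which pass their batteries with
  wide margins.
* No continuous-time solver is provided; the engine is the discrete
  difference system only.
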