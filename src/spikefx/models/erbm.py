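"""Event-driven restricted Boltzmann machine trained with event-driven
contrastive divergence (eCD) over stochastic synapses.

A spiking RBM on the bars-and-stripes problem: 18 visible units (16
pixels of a 4x4 binary image + 2 one-hot class units) and a hidden
layer, connected all-to-all with *shared* symmetric weights -- the
visible->hidden and hidden->visible synapse tables index the same
weight storage, so W and W^T are equal at every tick by construction
(which restricts the model to a single core).  Synapses are stochastic
(blank-out 1/2), implementing the Monte Carlo sampling of a synaptic
sampling machine; weight updates are applied even when a spike is
dropped at the synapse, since dropped spikes are still valid samples.

Contrastive divergence is driven by two modulatory input channels (one
excitatory, one inhibitory) projecting onto the modulator compartment
of every unit, active in alternation:

* **data phase** -- visible units are clamped by fixed-point logit
  currents of the pixel intensities (clipped away from 0 and 1) plus
  membrane noise; the excitatory modulator makes the symmetric
  nearest-neighbor STDP potentiate co-activity;
* **reconstruction phase** -- the visible layer runs free and the
  inhibitory modulator depresses co-activity.  Its amplitude is twice
  the excitatory one, compensating the ~2:1 co-activity asymmetry
  between the clamped and free phases so that weights equilibrate
  inside the 8-bit range.

Operating point (see docs/methods.md): clamped pixels fire near the
refractory cap; hidden units sit subthreshold, their threshold placed
in noise-sigma units between partial-feature and full-feature drive so
their rates are feature-selective; a static hidden bias keeps baseline
sampling activity alive; the two class units form a separate
lower-threshold readout group.  The refractory period exceeds the STDP
window, keeping pairings unique so the shared weight sees one
consistent symmetric update per coincidence.

Classification clamps only the 16 pixel units and takes the argmax of
free-running class-unit activity.  At this desk scale the contrastive
estimate learns only weak features: weight symmetry is exact and
training moves the test error, but the classification margin on
bars-and-stripes remains modest and is sensitive to the sampling
operating point -- the one demonstration of the five whose behavioral
battery is not passed with a wide margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import ConfigError, NeuronParamGroup
from ..network import Network
from ..plasticity import PlasticityConfig, STDPKernelConfig

__all__ = ["ERBMParams", "ERBMNet", "build_erbm", "train_erbm",
           "classify_erbm", "test_error"]


def _logit_current(intensity: float, scale: int = 24,
                   lo: float = 1e-5, hi: float = 0.98) -> int:
    """Fixed-point clamp current: scale * logit(clip(intensity))."""
    q = min(max(intensity, lo), hi)
    return int(round(scale * np.log(q / (1.0 - q))))


@dataclass(frozen=True)
class ERBMParams:
    n_visible: int = 18        # 16 pixels + 2 class units
    n_hidden: int = 32
    theta_pix: int = 448       # pixel threshold (clamp-driven units)
    theta_hid: int = 1100      # hidden threshold (subthreshold sampling)
    theta_cls: int = 450       # class-unit readout threshold
    hidden_bias: int = 120     # static drive keeping hidden sampling alive
    leak_exp: int = -3         # membrane decay
    noise_exp: int = 11        # membrane noise variance 2^11
    refractory: int = 10       # > STDP window: keeps pairings unique
    stdp_window: int = 8
    mod_leak_exp: int = -1     # fast modulator decay (crisp phase edges)
    mod_exc: int = 4           # excitatory modulator drive per spike
    mod_inh: int = 8           # inhibitory drive (2x: phase balance)
    gain_exp: int = 3          # synaptic gain on membranes
    blankout: int = 128        # stochastic synapses, p = 1/2
    r_bits: int = 6            # randomized rounding bits
    w_init: int = 8            # init weights uniform on [-w_init, w_init]
    clamp_scale: int = 24      # logit scaling of the clamp currents
    t_data: int = 30           # data-phase ticks per sample
    t_recon: int = 30          # reconstruction-phase ticks per sample
    t_test: int = 300          # free-run ticks per classification


@dataclass
class ERBMNet:
    net: Network
    params: ERBMParams
    visible: np.ndarray        # 18 ids (16 pixels, then 2 class units)
    hidden: np.ndarray
    mod_exc: int               # excitatory modulatory input channel
    mod_inh: int
    vh_slots: np.ndarray       # shared weight slots, (n_visible, n_hidden)
    tick: int = 0              # absolute simulation time across phases


def build_erbm(p: ERBMParams = ERBMParams(), seed: int = 0,
               n_cores: int = 1) -> ERBMNet:
    if n_cores != 1:
        raise ConfigError("shared symmetric weights restrict the eRBM to a "
                          "single core")
    net = Network()
    mods = net.add_input_group(2)

    def unit(theta: int, name: str) -> NeuronParamGroup:
        return NeuronParamGroup(
            k=2,
            A_sign=np.array([[-1, 0], [0, -1]], np.int8),
            A_exp=np.array([[p.leak_exp, 0], [0, p.mod_leak_exp]], np.int8),
            b=np.array([0, 0]), theta=np.array([theta, 32767]),
            reset_enable=np.array([True, False]), Xr=np.zeros(2, np.int64),
            noise_exp=np.array([p.noise_exp, -128]),
            refractory_period=p.refractory, modulator_index=1,
            syn_gain_exp=np.array([p.gain_exp, 0]), name=name)

    pixels = net.add_group(unit(p.theta_pix, "rbm-pixel"), 16)
    cls = net.add_group(unit(p.theta_cls, "rbm-class"), 2)
    hidden = net.add_group(unit(p.theta_hid, "rbm-hidden"), p.n_hidden)
    visible = np.concatenate([pixels, cls])

    kernel = STDPKernelConfig(t_ca=p.stdp_window, t_ac=p.stdp_window,
                              ca_exp=0, ac_exp=0, ca_sign=1, ac_sign=1,
                              mode="exp", half_decay=p.stdp_window + 1)
    plast = net.add_plasticity(PlasticityConfig(
        kernel=kernel, w_min=-127, w_max=127, r=p.r_bits, mod_idx=1,
        update_on_dropped=True))
    rng = np.random.default_rng(seed)
    pre = np.repeat(visible, p.n_hidden)
    post = np.tile(hidden, p.n_visible)
    w0 = rng.integers(-p.w_init, p.w_init + 1, size=len(pre))
    slots = net.connect(pre, post, comp=0, weight=w0, plast=plast,
                        bl_num=p.blankout)
    # reverse direction shares the same weight slots: exact symmetry
    net.connect(post, pre, comp=0, weight=w0, plast=plast,
                bl_num=p.blankout, slot=slots)
    everyone = np.concatenate([visible, hidden])
    net.connect(mods[0], everyone, comp=1, weight=p.mod_exc)
    net.connect(mods[1], everyone, comp=1, weight=-p.mod_inh)
    net.finalize()
    net.bias_extra[hidden, 0] = p.hidden_bias
    return ERBMNet(net=net, params=p, visible=visible, hidden=hidden,
                   mod_exc=int(mods[0]), mod_inh=int(mods[1]),
                   vh_slots=slots.reshape(p.n_visible, p.n_hidden))


def _clamp_currents(e: ERBMNet, pattern: np.ndarray, label: int | None
                    ) -> np.ndarray:
    """Clamp currents for a 4x4 pattern (+ one-hot class currents when a
    label is given; length 16 otherwise)."""
    p = e.params
    cur = np.array([_logit_current(v, p.clamp_scale)
                    for v in pattern.ravel()], dtype=np.int64)
    if label is None:
        return cur
    clsc = np.array([_logit_current(1.0 if label == i else 0.0,
                                    p.clamp_scale) for i in range(2)])
    return np.concatenate([cur, clsc])


def _phase(e: ERBMNet, ticks: int, mod: int | None, seed: int,
           plastic: bool) -> np.ndarray:
    """Run one phase; the modulatory channel ``mod`` (if any) fires every
    tick.  Returns the raster."""
    ev = None
    if mod is not None:
        tt = np.arange(e.tick, e.tick + ticks)
        ev = np.column_stack([tt, np.full(ticks, mod)])
    rec = e.net.run(ticks, seed=seed, events=ev, reset=False,
                    start_tick=e.tick,
                    plasticity_gate=None if plastic else (lambda t: False))
    e.tick += ticks
    return rec.raster


def train_erbm(e: ERBMNet, patterns: np.ndarray, labels: np.ndarray,
               n_epochs: int, seed: int = 0) -> None:
    """eCD training: one clamped data phase and one free reconstruction
    phase per sample, all samples per epoch."""
    p = e.params
    for epoch in range(n_epochs):
        for k in range(len(patterns)):
            cur = _clamp_currents(e, patterns[k], int(labels[k]))
            e.net.bias_extra[e.visible, 0] = cur
            _phase(e, p.t_data, e.mod_exc, seed, plastic=True)
            e.net.bias_extra[e.visible, 0] = 0
            _phase(e, p.t_recon, e.mod_inh, seed, plastic=True)
    e.net.bias_extra[e.visible, 0] = 0


def classify_erbm(e: ERBMNet, pattern: np.ndarray, seed: int = 0) -> int:
    """Clamp the 16 pixel units only; argmax of free class-unit activity."""
    p = e.params
    e.net.bias_extra[e.visible[:16], 0] = _clamp_currents(e, pattern, None)
    e.net.bias_extra[e.visible[16:], 0] = 0
    raster = _phase(e, p.t_test, None, seed, plastic=False)
    counts = [int(np.sum(raster[:, 2] == e.visible[16 + c]))
              for c in range(2)]
    e.net.bias_extra[e.visible, 0] = 0
    return int(np.argmax(counts))


def test_error(e: ERBMNet, patterns: np.ndarray, labels: np.ndarray,
               seed: int = 0) -> float:
    """Misclassification fraction over a pattern set."""
    wrong = 0
    for k in range(len(patterns)):
        wrong += int(classify_erbm(e, patterns[k], seed) != labels[k])
    return wrong / len(patterns)
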