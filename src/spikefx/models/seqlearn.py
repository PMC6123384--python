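"""Unsupervised spike-sequence learning with a voltage/calcium rule.

A post-synaptic membrane-potential dependent plasticity rule: unlike
STDP, weight updates are triggered *only* by pre-synaptic spikes, and
their sign and size are read off the post-synaptic state at that moment:

    Theta_m = eta_plus   if V >= V_lth     (LTP side)
            = eta_minus  otherwise         (LTD side)
    mod     = Theta_m - eta_h * (Ca_set - Ca),   eta_h < 0
    dw_j    = mod  on every spike of pre-synaptic input j

where Ca is a calcium trace of the neuron's own firing (incremented by
gamma per output spike, decaying slowly) and the eta_h term is a
homeostatic correction toward the calcium set point.

State mapping onto a 4-component neuron:

* ``x0 = V``        -- membrane, driven by the 100 plastic input synapses;
* ``x1 = Ca``       -- calcium trace, pumped by a self-synapse (autapse);
* ``x2 = Theta_m``  -- LTP/LTD switch, a hardware comparator on ``x0``;
* ``x3 = mod``      -- the weight-update magnitude, recomputed every tick
  from ``x2`` and ``x1`` (a one-tick-lag instantaneous combination);
  the plasticity engine commits ``x3`` verbatim on each pre spike
  (state-driven mode, the acausal pipeline alone).

The task: 100 Poisson inputs project to 5 learning neurons; a frozen
random spike pattern is presented repeatedly, interleaved with fresh
random segments of the same rate.  Because only the pattern recurs, the
voltage-gated feedback potentiates the pattern-active synapses and the
outputs become selective: after training they fire several-fold faster
inside pattern windows than in noise segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import Comparator, NeuronParamGroup
from ..network import Network, SimRecord
from ..plasticity import PlasticityConfig, STDPKernelConfig
from ..synth import embedded_pattern_trains

__all__ = ["SeqLearnParams", "build_seqlearn", "train_seqlearn",
           "selectivity"]


@dataclass(frozen=True)
class SeqLearnParams:
    """Neuron and rule constants (eta_plus/eta_minus are the LTP/LTD
    magnitudes; exponents are the power-of-two decay rates)."""

    n_inputs: int = 100
    n_outputs: int = 5
    tau_m_exp: int = -3        # membrane decay 2^-3 per tick
    tau_ca_exp: int = -8       # calcium decay 2^-8 per tick
    gamma: int = 127           # calcium autapse weight per output spike
    gamma_gain: int = 2        # gain shift on the calcium compartment
    theta: int = 800           # firing threshold on V
    V_lth: int = 620           # LTP/LTD membrane switch
    eta_plus: int = 8
    eta_minus: int = -2
    eta_h_exp: int | None = -7  # homeostasis shift (|eta_h| = 2^-7); None
                                # disables the homeostatic term
    ca_set: int = 1024         # calcium set point
    refractory: int = 10
    w_init_max: int = 48       # initial weights uniform on [0, w_init_max]
    w_max: int = 127
    rate_hz: float = 20.0
    pattern_len: int = 50
    noise_len: int = 50


def build_seqlearn(p: SeqLearnParams = SeqLearnParams(), seed: int = 0
                   ) -> tuple[Network, np.ndarray, np.ndarray]:
    """Returns (network, input ids, output ids); input->output weights are
    initialized uniformly at random from [0, w_init_max]."""
    net = Network()
    inputs = net.add_input_group(p.n_inputs)
    # x3 <- x2 + 2^eta_h_exp * (ca_set - x1), refreshed every tick
    # (eta_h negative: firing above the calcium set point pushes mod down)
    eh = p.eta_h_exp
    A_sign = np.array([
        [-1, 0, 0, 0],
        [0, -1, 0, 0],
        [0, 0, 0, 0],          # x2 is set by the comparator, not by A
        [0, -1 if eh is not None else 0, 1, -1],
    ], dtype=np.int8)
    A_exp = np.array([
        [p.tau_m_exp, 0, 0, 0],
        [0, p.tau_ca_exp, 0, 0],
        [0, 0, 0, 0],
        [0, eh if eh is not None else 0, 0, 0],
    ], dtype=np.int8)
    if eh is None:
        eta_h_times_set = 0
    else:
        eta_h_times_set = (p.ca_set >> -eh) if eh < 0 else (p.ca_set << eh)
    g = NeuronParamGroup(
        k=4, A_sign=A_sign, A_exp=A_exp,
        b=np.array([0, 0, 0, eta_h_times_set]),
        theta=np.array([p.theta, 32767, 32767, 32767]),
        reset_enable=np.array([True, False, False, False]),
        Xr=np.zeros(4, dtype=np.int64),
        refractory_period=p.refractory,
        modulator_index=3,
        syn_gain_exp=np.array([0, p.gamma_gain, 0, 0]),
        comparator=Comparator(target=2, source=0, threshold=p.V_lth,
                              value_ge=p.eta_plus, value_lt=p.eta_minus),
        name="seqlearn")
    outputs = net.add_group(g, p.n_outputs)
    cfg = net.add_plasticity(PlasticityConfig(
        kernel=STDPKernelConfig(t_ca=1, t_ac=1, ca_exp=0, ca_sign=1),
        w_min=0, w_max=p.w_max, r=0, mod_idx=3, state_driven=True))
    rng = np.random.default_rng(seed)
    pre = np.repeat(inputs, p.n_outputs)
    post = np.tile(outputs, p.n_inputs)
    w0 = rng.integers(0, p.w_init_max + 1, size=len(pre))
    net.connect(pre, post, comp=0, weight=w0, plast=cfg)
    # calcium autapses: each output pumps its own x1 by gamma when it fires
    net.connect(outputs, outputs, comp=1, weight=p.gamma)
    net.finalize()
    return net, inputs, outputs


def train_seqlearn(p: SeqLearnParams = SeqLearnParams(), n_repeats: int = 200,
                   seed: int = 0) -> tuple[SimRecord, list, np.ndarray]:
    """Run the embedded-pattern task; returns (record, pattern windows,
    output ids)."""
    net, inputs, outputs = build_seqlearn(p, seed=seed)
    events, windows = embedded_pattern_trains(
        n_inputs=p.n_inputs, pattern_len=p.pattern_len, n_repeats=n_repeats,
        noise_len=p.noise_len, rate_hz=p.rate_hz, seed=seed)
    ticks = windows[-1][1] + p.noise_len
    rec = net.run(ticks, seed=seed, events=events, record_weights=True)
    return rec, windows, outputs


def selectivity(rec: SimRecord, windows, outputs, tail_frac: float = 0.25
                ) -> np.ndarray:
    """Per-output ratio of firing rate inside pattern windows to the rate
    outside them, over the last ``tail_frac`` of the run (post-training)."""
    t0 = rec.n_ticks * (1.0 - tail_frac)
    in_pat = np.zeros(rec.n_ticks + 1, dtype=bool)
    for a, b in windows:
        in_pat[a:b] = True
    ratios = []
    for gid in outputs:
        s = rec.spikes_of(gid)
        s = s[s >= t0]
        n_in = int(in_pat[s].sum())
        n_out = len(s) - n_in
        ticks_in = int(in_pat[int(t0):rec.n_ticks].sum())
        ticks_out = (rec.n_ticks - int(t0)) - ticks_in
        rate_in = n_in / max(ticks_in, 1)
        rate_out = n_out / max(ticks_out, 1)
        ratios.append(rate_in / rate_out if rate_out > 0
                      else (np.inf if rate_in > 0 else 0.0))
    return np.array(ratios)
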