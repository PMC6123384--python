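"""Event-driven random back-propagation (eRBP): supervised learning with
spiking error neurons and a fixed random feedback projection.

Architecture (feed-forward, two plastic stages):

* **data** neurons (Poisson inputs) -> **hidden** -> **prediction**, with
  stochastic (blank-out) synapses;
* one **label** channel per class emits a regular spike train (inter-spike
  interval = the prediction refractory period) for the true class;
* per class, a pair of **error neurons** -- one for positive error, one
  for negative -- integrate prediction and label spikes with opposing
  signs (non-leaky, membrane floored at 0, reset on threshold), so their
  firing rate is a linear rectification of the rate mismatch; when the
  prediction matches the label they stay silent;
* error spikes are fed back: one-to-one (signed) onto the modulator
  compartment of the prediction neurons, and through a *fixed random
  zero-sum* projection onto the modulator compartment of each hidden
  neuron -- the random-back-propagation trick that avoids weight
  transport.

Hidden and prediction neurons have two components: ``x0 = V`` (membrane,
first-order filter of synaptic events, threshold/reset/refractory) and
``x1 = m`` (modulator, filtering the error feedback).  The plasticity is
the error-modulated, membrane-gated, pre-spike-triggered rule

    dw  proportional to  m * boxcar(V) * s_pre(t)

with 8-bit weights and r = 6 randomized-rounding bits.  Weight updates
are frozen during the first ticks of each pattern presentation so that
transients between patterns are not learned.

The training task here is a two-class synthetic Poisson-pattern problem
(16 inputs, 10 hidden, 2 classes by default): each class is a fixed
random half-on pixel mask, presented as Poisson rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import NeuronParamGroup
from ..network import Network
from ..plasticity import PlasticityConfig, STDPKernelConfig

__all__ = ["ERBPParams", "ERBPNet", "build_erbp", "make_task", "train_erbp"]


@dataclass(frozen=True)
class ERBPParams:
    """Layer sizes, neuron constants and learning constants."""

    n_data: int = 16
    n_hidden: int = 10
    n_classes: int = 2
    tau_syn_exp: int = -4      # membrane filter of hidden/prediction units
    tau_m_exp: int = -4        # modulator filter
    theta_h: int = 400         # hidden threshold
    theta_p: int = 300         # prediction threshold
    tau_refr: int = 10         # refractory; label ISI equals this
    gain_exp: int = 2          # synaptic gain shift on membranes
    boxcar_min: int = -400     # membrane gate lower bound
    boxcar_max: int = 400      # membrane gate upper bound
    w_label: int = 64          # label/prediction drive onto error neurons
    theta_err: int = 384       # error threshold (a multiple of w_label)
    g_feedback: int = 24       # magnitude scale of random error feedback
    g_pred_fb: int = 32        # one-to-one error -> prediction feedback
    blankout: int = 128        # blank-out numerator (p = 128/256 = 1/2)
    r_bits: int = 6            # randomized rounding bits
    w_init: int = 16           # init weights uniform on [-w_init, w_init]
    rate_hi: float = 50.0      # "on" pixel Poisson rate (Hz)
    rate_lo: float = 4.0       # "off" pixel rate (Hz)
    t_present: int = 250       # ticks per pattern presentation
    t_freeze: int = 60         # no weight updates at presentation start


@dataclass
class ERBPNet:
    """A built eRBP network and its population ids."""

    net: Network
    params: ERBPParams
    data: np.ndarray
    labels: np.ndarray
    hidden: np.ndarray
    pred: np.ndarray
    err_pos: np.ndarray
    err_neg: np.ndarray


def _vm_group(theta: int, p: ERBPParams, name: str) -> NeuronParamGroup:
    """Two-component membrane + modulator neuron (hidden/prediction)."""
    A_sign = np.array([[-1, 0], [0, -1]], dtype=np.int8)
    A_exp = np.array([[p.tau_syn_exp, 0], [0, p.tau_m_exp]], dtype=np.int8)
    return NeuronParamGroup(
        k=2, A_sign=A_sign, A_exp=A_exp, b=np.zeros(2, dtype=np.int64),
        theta=np.array([theta, 32767]),
        reset_enable=np.array([True, False]), Xr=np.zeros(2, dtype=np.int64),
        refractory_period=p.tau_refr, modulator_index=1,
        syn_gain_exp=np.array([p.gain_exp, 0]), name=name)


def build_erbp(p: ERBPParams = ERBPParams(), seed: int = 0) -> ERBPNet:
    net = Network()
    data = net.add_input_group(p.n_data)
    labels = net.add_input_group(p.n_classes)
    hidden = net.add_group(_vm_group(p.theta_h, p, "hidden"), p.n_hidden)
    pred = net.add_group(_vm_group(p.theta_p, p, "prediction"), p.n_classes)
    # error neurons: non-leaky integrators, floored at 0, reset on
    # crossing; firing rate ~ rectified rate difference
    err_g = NeuronParamGroup(
        k=1, A_sign=np.zeros((1, 1), np.int8), A_exp=np.zeros((1, 1), np.int8),
        b=np.zeros(1, dtype=np.int64), theta=np.array([p.theta_err]),
        reset_enable=np.array([True]), Xr=np.zeros(1, dtype=np.int64),
        x_min=np.zeros(1, dtype=np.int64), name="error")
    err_pos = net.add_group(err_g, p.n_classes)
    err_neg = net.add_group(err_g, p.n_classes)

    plast = net.add_plasticity(PlasticityConfig(
        kernel=STDPKernelConfig(t_ca=1, t_ac=1, ca_exp=0, ca_sign=1),
        w_min=-128, w_max=127, r=p.r_bits, mod_idx=1,
        gate_comp=0, gate_min=p.boxcar_min, gate_max=p.boxcar_max,
        state_driven=True))

    rng = np.random.default_rng(seed)
    # data -> hidden (plastic, stochastic)
    pre = np.repeat(data, p.n_hidden)
    post = np.tile(hidden, p.n_data)
    w0 = rng.integers(-p.w_init, p.w_init + 1, size=len(pre))
    net.connect(pre, post, comp=0, weight=w0, plast=plast, bl_num=p.blankout)
    # hidden -> prediction (plastic, stochastic)
    pre = np.repeat(hidden, p.n_classes)
    post = np.tile(pred, p.n_hidden)
    w0 = rng.integers(-p.w_init, p.w_init + 1, size=len(pre))
    net.connect(pre, post, comp=0, weight=w0, plast=plast, bl_num=p.blankout)
    # prediction/label -> error pairs (one-to-one, opposing signs)
    net.connect(pred, err_pos, comp=0, weight=p.w_label)
    net.connect(labels, err_pos, comp=0, weight=-p.w_label)
    net.connect(pred, err_neg, comp=0, weight=-p.w_label)
    net.connect(labels, err_neg, comp=0, weight=p.w_label)
    # error -> prediction modulator (one-to-one, signed)
    net.connect(err_pos, pred, comp=1, weight=-p.g_pred_fb)
    net.connect(err_neg, pred, comp=1, weight=p.g_pred_fb)
    # error -> hidden modulator: fixed random zero-sum projection
    for h in hidden:
        g = rng.integers(p.g_feedback // 2, p.g_feedback + 1,
                         size=p.n_classes)
        sign = int(rng.choice([-1, 1]))
        for i in range(p.n_classes):
            s = sign if i % 2 == 0 else -sign
            net.connect(err_pos[i], h, comp=1, weight=int(-s * g[i]))
            net.connect(err_neg[i], h, comp=1, weight=int(s * g[i]))
    net.finalize()
    return ERBPNet(net=net, params=p, data=data, labels=labels, hidden=hidden,
                   pred=pred, err_pos=err_pos, err_neg=err_neg)


def make_task(p: ERBPParams, seed: int = 0) -> np.ndarray:
    """Per-class fixed random half-on pixel masks as Poisson rates:
    (n_classes, n_data)."""
    rng = np.random.default_rng(seed + 1000003)
    rates = np.full((p.n_classes, p.n_data), p.rate_lo)
    for c in range(p.n_classes):
        on = rng.permutation(p.n_data)[: p.n_data // 2]
        rates[c, on] = p.rate_hi
    return rates


def _presentation_events(e: ERBPNet, rates: np.ndarray, classes, t0: int,
                         seed: int, with_labels: bool) -> np.ndarray:
    """Poisson data events (+ regular label spikes) for a sequence of
    pattern presentations starting at tick ``t0``."""
    p = e.params
    rng = np.random.default_rng(seed)
    out = []
    for k, c in enumerate(classes):
        start = t0 + k * p.t_present
        draws = rng.random((p.t_present, p.n_data))
        tt, cc = np.nonzero(draws < rates[c] / 1000.0)
        out.append(np.column_stack([start + tt, e.data[cc]]))
        if with_labels:
            lt = np.arange(start, start + p.t_present, p.tau_refr)
            out.append(np.column_stack([lt, np.full(len(lt), e.labels[c])]))
    ev = np.vstack(out)
    return ev[np.argsort(ev[:, 0], kind="stable")]


def _accuracy(e: ERBPNet, rates: np.ndarray, classes, seed: int) -> float:
    """Fraction of presentations whose prediction-layer spike-count argmax
    matches the class (labels off, plasticity off, weights kept)."""
    p = e.params
    ev = _presentation_events(e, rates, classes, 0, seed, with_labels=False)
    rec = e.net.run(len(classes) * p.t_present, seed=seed, events=ev,
                    plasticity_gate=lambda t: False)
    correct = 0
    for k, c in enumerate(classes):
        a, b = k * p.t_present, (k + 1) * p.t_present
        counts = [np.sum((rec.raster[:, 0] >= a) & (rec.raster[:, 0] < b)
                         & (rec.raster[:, 2] == pid)) for pid in e.pred]
        correct += int(np.argmax(counts) == c)
    return correct / len(classes)


def train_erbp(p: ERBPParams = ERBPParams(), n_present: int = 500,
               seed: int = 0, eval_every: int | None = None,
               n_eval: int = 20):
    """Train on the synthetic two-class task and track held-out accuracy.

    Returns (accuracies, checkpoints, net): ``accuracies[i]`` is the
    evaluation accuracy after ``checkpoints[i]`` presentations
    (checkpoint 0 is the untrained network).
    """
    if eval_every is None:
        eval_every = n_present // 2
    rates = make_task(p, seed)
    e = build_erbp(p, seed=seed)
    rng = np.random.default_rng(seed + 7)
    classes = rng.integers(0, p.n_classes, size=n_present)
    eval_classes = np.tile(np.arange(p.n_classes),
                           n_eval // p.n_classes + 1)[:n_eval]
    accs = [_accuracy(e, rates, eval_classes, seed + 99)]
    checkpoints = [0]
    done = 0
    while done < n_present:
        block = min(eval_every, n_present - done)
        ev = _presentation_events(e, rates, classes[done:done + block], 0,
                                  seed + 13 + done, with_labels=True)
        gate = lambda t: (t % p.t_present) >= p.t_freeze  # noqa: E731
        e.net.run(block * p.t_present, seed=seed + done, events=ev,
                  plasticity_gate=gate)
        done += block
        accs.append(_accuracy(e, rates, eval_classes, seed + 99))
        checkpoints.append(done)
    return np.array(accs), np.array(checkpoints), e
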