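"""Amari neural-field dynamics on a spiking lattice.

A neural field describes the average activity u(r, t) of a cortical sheet:

    tau du/dt = -u + h + I_ext + integral w(|r - r'|) f(u(r')) dr'

with a Heaviside transfer function f and a difference-of-Gaussians (DoG)
lateral kernel  w(r) = K_e exp(-r^2 / 2 sigma_e^2) - K_i exp(-r^2 / 2
sigma_i^2).  Because f is a step function, each field unit maps onto a
leaky integrate-and-fire neuron whose *reset is disabled*: a unit above
threshold fires every tick (its spike train is the Heaviside indicator),
so the recurrent spiking input reproduces the integral term tick by tick.

The lattice has 100 internal one-component units, all-to-all connected
with the uniform-quantized kernel, and 100 external Poisson channels
connected one-to-one.  Three presets reproduce the classic behaviors:

* ``stationary-bump`` -- a localized stimulus (35 Hz on units 40-60, 10 Hz
  elsewhere, 400 ticks) ignites a self-sustained bump that persists long
  after the input is removed;
* ``action-selection`` -- two competing stimuli (50 Hz on units 20-40 and
  70-90, 500 ticks); broad inhibition forces a single winner that remains
  active after stimulus removal;
* ``tracking-asymmetric`` -- an asymmetric (shifted-excitation) kernel and
  a 50 Hz input patch displaced every 500 ticks; the bump follows the
  moving target.

Total simulated time is 2500 ticks per preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import NeuronParamGroup
from ..network import Network, SimRecord
from ..synth import SpikeTrainSpec, poisson_trains

__all__ = ["FieldParams", "PRESETS", "quantize", "dog_kernel", "build_field",
           "input_events", "run_field", "activity_profile", "bump_center"]

N_UNITS = 100
TOTAL_TICKS = 2500


def quantize(r, delta: float):
    """Uniform quantizer Q(r) = delta * floor(r / delta + 0.5)."""
    return delta * np.floor(np.asarray(r, dtype=float) / delta + 0.5)


@dataclass(frozen=True)
class FieldParams:
    """Lattice size, DoG kernel constants, quantizer step and input spec."""

    n: int = N_UNITS
    K_e: float = 0.65
    sigma_e: float = 4.0
    K_i: float = 0.20
    sigma_i: float = 10.0
    shift: float = 0.0           # displaces the excitatory lobe (asymmetry)
    delta: float = 1.0 / 128.0   # quantizer step; also the 8-bit weight LSB
    h: int = -40                 # resting drive (negative)
    leak_exp: int = -4
    input_weight: int = 127
    input_gain: int = 3          # gain on the input-current compartment
    input_leak: int = -6         # decay of the input current (integration)
    input_coup: int = -4         # coupling of input current into the field
    theta: int = 2000
    # schedule entries: (t0, t1, c0, c1, rate_hz)
    schedule: tuple = ()


PRESETS: dict[str, FieldParams] = {
    "stationary-bump": FieldParams(
        schedule=((0, 400, 40, 61, 35.0), (0, 400, 0, 40, 10.0),
                  (0, 400, 61, 100, 10.0))),
    "action-selection": FieldParams(
        K_i=0.21, sigma_i=30.0,
        schedule=((0, 500, 20, 41, 50.0), (0, 500, 70, 91, 50.0))),
    "tracking-asymmetric": FieldParams(
        K_i=0.21, sigma_i=30.0, shift=1.0,
        schedule=tuple((500 * k, 500 * (k + 1), c, c + 11, 50.0)
                       for k, c in enumerate((15, 30, 45, 60, 75)))),
}


def dog_kernel(p: FieldParams) -> np.ndarray:
    """Difference-of-Gaussians lateral weights (n, n); ``shift`` moves the
    excitatory lobe off-center, giving the asymmetric tracking kernel."""
    idx = np.arange(p.n)
    d = idx[None, :] - idx[:, None]  # displacement from i to j
    exc = p.K_e * np.exp(-((d - p.shift) ** 2) / (2 * p.sigma_e**2))
    inh = p.K_i * np.exp(-(d**2) / (2 * p.sigma_i**2))
    return exc - inh


def build_field(preset: str) -> tuple[Network, np.ndarray, np.ndarray]:
    """Returns (network, input channel ids, field unit ids)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    net = Network()
    inputs = net.add_input_group(p.n)
    # two compartments: x0 = field potential (recurrent input, gain 1);
    # x1 = fast input current smoothing the sparse external events
    A_sign = np.array([[-1, 1], [0, -1]], dtype=np.int8)
    A_exp = np.array([[p.leak_exp, p.input_coup], [0, p.input_leak]],
                     dtype=np.int8)
    g = NeuronParamGroup(
        k=2, A_sign=A_sign, A_exp=A_exp,
        b=np.array([p.h, 0]), theta=np.array([p.theta, 32767]),
        reset_enable=np.array([False, False]),  # no reset: Heaviside coding
        Xr=np.array([0, 0]), syn_gain_exp=np.array([0, p.input_gain]),
        name=f"field-{preset}")
    units = net.add_group(g, p.n)
    w = np.clip(np.round(quantize(dog_kernel(p), p.delta) / p.delta),
                -127, 127).astype(np.int64)
    np.fill_diagonal(w, 0)  # no self-excitation
    pre, post = np.nonzero(w)
    net.connect(units[pre], units[post], comp=0, weight=w[pre, post])
    net.connect(inputs, units, comp=1, weight=p.input_weight)
    net.finalize()
    return net, inputs, units


def input_events(preset: str, seed: int = 0) -> np.ndarray:
    p = PRESETS[preset]
    spec = SpikeTrainSpec(n_channels=p.n, schedule=p.schedule)
    return poisson_trains(spec, seed)


def run_field(preset: str, ticks: int = TOTAL_TICKS, seed: int = 0) -> SimRecord:
    net, inputs, units = build_field(preset)
    ev = input_events(preset, seed)
    return net.run(ticks, seed=seed, events=ev)


def activity_profile(rec: SimRecord, units: np.ndarray, t0: int, t1: int
                     ) -> np.ndarray:
    """Spike count of each field unit over ticks [t0, t1)."""
    r = rec.raster
    sel = (r[:, 0] >= t0) & (r[:, 0] < t1) & np.isin(r[:, 2], units)
    counts = np.bincount(r[sel, 2], minlength=int(units.max()) + 1)
    return counts[units]


def bump_center(profile: np.ndarray) -> float:
    """Activity-weighted mean index of a profile (nan when silent)."""
    total = profile.sum()
    if total == 0:
        return float("nan")
    return float((np.arange(len(profile)) * profile).sum() / total)
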