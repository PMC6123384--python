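"""Mihalas-Niebur style generalized integrate-and-fire behaviors.

The Mihalas-Niebur neuron (MNN) is a linear leaky integrate-and-fire model
with an adaptive threshold and internal after-spike currents that
reproduces a large repertoire of firing behaviors.  The simulator spikes on
a *fixed* threshold of state component 0, so the builder uses a difference
coordinate: component 0 carries ``d = V - Theta`` (membrane minus
instantaneous threshold) and spikes at ``d >= theta_0``; threshold
adaptation and after-spike currents live in the remaining components and
couple into ``d`` through power-of-two coefficients.

State mapping used by the presets (k = 3):

* ``x0 = d`` -- effective distance to threshold (spiking compartment),
* ``x1 = u`` -- adaptation: either integrates the depolarization
  (threshold adaptation, MNN constant ``a``) or is pumped by an autapse on
  each spike (after-spike current, MNN reset constant ``P_j``), and decays
  with its own rate (``b`` resp. ``k_j``); it couples negatively into
  ``d``,
* ``x2`` -- second internal current where needed.

Preset parameters are integer re-derivations in this coordinate system:
the published continuous constants do not map exactly onto signed
powers of two, so the acceptance surface is the qualitative behavior
class (inter-spike-interval statistics, f-I curve shape), not trajectory
equality.  :class:`MNNParams` carries continuous constants and performs
the nearest-power-of-two conversion for user-defined cells.

Behavior classifiers (:func:`classify`) operate on spike trains / f-I
curves and are mutually discriminative: each preset passes its own
classifier, and every classifier rejects at least one other preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import NeuronParamGroup
from ..fxp import ShiftCoeff
from ..network import Network, SimRecord

__all__ = ["MNNParams", "PRESETS", "build_mnn", "run_preset", "fi_curve",
           "classify", "CLASSIFIERS"]

THETA0 = 1024  # fixed spike threshold on the difference state


@dataclass(frozen=True)
class MNNParams:
    """Continuous MNN constants (one neuron, two internal currents).

    ``to_shift_coeffs`` rounds the derived coupling coefficients of the
    difference-coordinate system to the nearest signed powers of two.
    """

    C_m: float = 1.0
    I_e: float = 1.5
    g: float = 0.05
    E_L: float = 0.0
    a: float = 0.0
    b: float = 0.01
    Theta_inf: float = 1.0
    k_1: float = 0.2
    k_2: float = 0.02
    R_1: float = 0.0
    R_2: float = 1.0
    P_1: float = 0.0
    P_2: float = 0.0
    V_r: float = 0.0
    Theta_r: float = 1.0

    def to_shift_coeffs(self) -> dict[str, ShiftCoeff]:
        gm = self.g / self.C_m
        return {
            "d_leak": ShiftCoeff.from_float(-(gm + self.a)),
            "d_from_u": ShiftCoeff.from_float(-(gm + self.a - self.b)),
            "u_from_d": ShiftCoeff.from_float(self.a),
            "u_leak": ShiftCoeff.from_float(-self.b),
            "i1_leak": ShiftCoeff.from_float(-self.k_1),
            "i2_leak": ShiftCoeff.from_float(-self.k_2),
        }


# Integer presets in the difference coordinate system.  Fields:
#   e0    : membrane leak exponent (coefficient -2^e0 on x0)
#   bias  : constant drive b0
#   reset : Xr0 (membrane reset in difference coordinates)
#   refr  : refractory ticks
#   aux   : auxiliary components (threshold adaptation / after-spike
#           currents), each a dict with
#             coup  : (sign, exponent) coupling into d
#             leak  : own decay exponent
#             drive : ("state", exponent)  -- integrates 2^exponent * d
#                     (threshold adaptation, MNN constant a), or
#                     ("spike", weight, gain_exp) -- pumped by an autapse
#                     on every spike (after-spike current, MNN reset
#                     constant P_j)
PRESETS: dict[str, dict] = {
    "tonic":       dict(e0=-4, bias=96, reset=0, refr=4, aux=[]),
    "phasic":      dict(e0=-4, bias=128, reset=0, refr=4, aux=[
                        dict(coup=(-1, -2), leak=-9, drive=("state", -7))]),
    "mixed":       dict(e0=-4, bias=144, reset=0, refr=4, aux=[
                        dict(coup=(-1, -3), leak=-7, drive=("state", -7))]),
    "tonic-burst": dict(e0=-4, bias=80, reset=0, refr=2, aux=[
                        dict(coup=(1, -3), leak=-4, drive=("spike", 127, 2)),
                        dict(coup=(-1, -2), leak=-8, drive=("spike", 32, 0))]),
    "classI":      dict(e0=-4, bias=68, reset=0, refr=4, aux=[]),
    "classII":     dict(e0=-4, bias=72, reset=960, refr=8, theta=1025, aux=[]),
}


def build_mnn(preset: str, bias: int | None = None) -> Network:
    """One MNN-style neuron (plus autapses where the preset uses
    after-spike currents)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    k = 1 + len(p["aux"])
    A_sign = np.zeros((k, k), dtype=np.int8)
    A_exp = np.zeros((k, k), dtype=np.int8)
    A_sign[0, 0], A_exp[0, 0] = -1, p["e0"]
    gains = [0] * k
    for c, aux in enumerate(p["aux"], start=1):
        A_sign[0, c], A_exp[0, c] = aux["coup"]
        A_sign[c, c], A_exp[c, c] = -1, aux["leak"]
        if aux["drive"][0] == "state":
            A_sign[c, 0], A_exp[c, 0] = 1, aux["drive"][1]
        else:
            gains[c] = aux["drive"][2]
    g = NeuronParamGroup(
        k=k, A_sign=A_sign, A_exp=A_exp,
        b=np.array([bias if bias is not None else p["bias"]] + [0] * (k - 1)),
        theta=np.array([p.get("theta", THETA0)] + [32767] * (k - 1)),
        reset_enable=np.array([True] + [False] * (k - 1)),
        Xr=np.array([p["reset"]] + [0] * (k - 1)),
        syn_gain_exp=np.array(gains),
        refractory_period=p["refr"], name=f"mnn-{preset}")
    net = Network()
    nid = net.add_group(g, 1)[0]
    for c, aux in enumerate(p["aux"], start=1):
        if aux["drive"][0] == "spike":
            net.connect(nid, nid, comp=c, weight=aux["drive"][1])
    net.finalize()
    return net


def run_preset(preset: str, ticks: int = 1000, seed: int = 0,
               bias: int | None = None) -> SimRecord:
    net = build_mnn(preset, bias=bias)
    return net.run(ticks, seed=seed, watch=[0])


def fi_curve(preset: str, biases, ticks: int = 2000, seed: int = 0) -> np.ndarray:
    """Firing rate (Hz, at 1 tick = 1 ms) for each constant drive value."""
    rates = []
    for b in biases:
        rec = run_preset(preset, ticks=ticks, seed=seed, bias=int(b))
        rates.append(len(rec.raster) / ticks * 1000.0)
    return np.array(rates)


# ---------------------------------------------------------------------------
# behavior classifiers
# ---------------------------------------------------------------------------

def _isis(spikes: np.ndarray) -> np.ndarray:
    return np.diff(np.sort(spikes))


def classify_tonic(spikes: np.ndarray, ticks: int) -> bool:
    """Sustained regular firing: many spikes spanning the run, ISI
    coefficient of variation < 0.1 after the transient."""
    if len(spikes) < 10 or spikes.max() < 0.75 * ticks:
        return False
    isis = _isis(spikes)
    steady = isis[len(isis) // 4:]
    return steady.std() / steady.mean() < 0.1


def classify_phasic(spikes: np.ndarray, ticks: int) -> bool:
    """At least one spike, all within the first quarter of the run."""
    return len(spikes) >= 1 and spikes.max() < ticks / 4


def classify_burst(spikes: np.ndarray, ticks: int) -> bool:
    """Bimodal ISI distribution: short intra-burst and long inter-burst
    intervals separated by a wide gap."""
    isis = _isis(spikes)
    if len(isis) < 8:
        return False
    thr = np.sqrt(isis.min() * isis.max())
    short, long_ = isis[isis < thr], isis[isis >= thr]
    if len(short) < 4 or len(long_) < 3:
        return False
    return long_.mean() / short.mean() >= 4.0


def classify_mixed(spikes: np.ndarray, ticks: int) -> bool:
    """Initial fast burst settling into sustained slower tonic firing."""
    if len(spikes) < 8 or spikes.max() < 0.75 * ticks:
        return False
    isis = _isis(spikes)
    early = isis[:3].mean()
    late = isis[-3:].mean()
    if early > 0.5 * late:  # clearly faster at onset than once settled
        return False
    tail = isis[-5:]
    return tail.std() / tail.mean() < 0.2


_FI_BIASES = np.arange(56, 132, 4)


def classify_class1(rates: np.ndarray) -> bool:
    """Continuous f-I onset: firing can be arbitrarily slow near rheobase."""
    nz = rates[rates > 0]
    return len(nz) > 0 and nz.min() <= 20.0


def classify_class2(rates: np.ndarray) -> bool:
    """Discontinuous f-I onset: a jump from silence to fast firing."""
    nz = rates[rates > 0]
    return 0 < len(nz) < len(rates) and nz.min() >= 40.0


CLASSIFIERS = {
    "tonic": classify_tonic,
    "phasic": classify_phasic,
    "mixed": classify_mixed,
    "tonic-burst": classify_burst,
    "classI": classify_class1,
    "classII": classify_class2,
}


def classify(preset: str, name: str, ticks: int = 1000, seed: int = 0) -> bool:
    """Does ``preset``'s output pass the classifier of behavior ``name``?"""
    fn = CLASSIFIERS[name]
    if name in ("classI", "classII"):
        return bool(fn(fi_curve(preset, _FI_BIASES, seed=seed)))
    rec = run_preset(preset, ticks=ticks, seed=seed)
    return bool(fn(rec.spikes_of(0), ticks))
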