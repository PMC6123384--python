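"""Per-tick neuron state integration, threshold/reset logic and accumulation.

Neurons are multi-compartment linear units: each neuron carries ``k`` state
components (1-8) coupled through a transition matrix whose entries are
signed powers of two (:class:`~spikefx.fxp.ShiftCoeff`).  One tick updates

``x[t+1] = saturate(x[t] + A <> x[t] + acc[t] + eta[t] + b)``

where ``A <> x`` applies the leak operator entrywise, ``acc`` is the
synaptic input accumulated during the *previous* tick's second stage,
``eta`` is keyed integer noise and ``b`` a constant bias.  Component 0 is
the spiking compartment: when it reaches its threshold the neuron emits a
spike, is clamped at its reset value for a programmable refractory period,
and any component whose reset is enabled and whose threshold is crossed is
set to its reset value (resets on components other than 0 fire
independently of spiking, which is how adaptive thresholds and calcium
floors are built).

Groups of neurons share one :class:`NeuronParamGroup`; all per-tick maths
is vectorized over the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fxp
from .fxp import DEFAULT_WIDTH, MAX_EXP

__all__ = ["NeuronParamGroup", "Comparator", "GroupState", "ConfigError",
           "NOISE_OFF", "shift_mult_varexp"]

NOISE_OFF = -128  # sentinel: noise disabled on a component
MAX_K = 8


class ConfigError(ValueError):
    """Raised for inconsistent neuron/synapse configuration."""


@dataclass(frozen=True)
class Comparator:
    """Hardware-style threshold unit evaluated at the end of stage 1:
    ``x[target] = value_ge if x[source] >= threshold else value_lt``.

    This is the one nonlinear state element besides threshold/reset; it is
    what lets a state component encode a membrane-voltage comparison (e.g.
    the LTP/LTD switch of voltage-based sequence-learning rules).
    """

    target: int
    source: int
    threshold: int
    value_ge: int
    value_lt: int


@dataclass
class NeuronParamGroup:
    """All per-group neuron constants.

    Parameters
    ----------
    k : number of state components per neuron (1-8).
    A_sign, A_exp : (k, k) transition matrix as sign/exponent arrays;
        entry (i, j) is the coupling of component j into component i.
    b : (k,) constant input per component.
    theta : (k,) thresholds.
    reset_enable : (k,) whether crossing theta_i resets component i to Xr_i.
    Xr : (k,) reset values.  Xr[0] is also the refractory clamp value.
    noise_exp : (k,) variance exponents of the additive noise
        (``NOISE_OFF`` disables noise on a component).
    refractory_period : ticks during which component 0 is clamped after a
        spike.
    modulator_index : which component serves as the plasticity modulator
        for synapses onto these neurons.
    syn_gain_exp : (k,) shift applied to synaptic weights accumulated onto
        each component (the "predefined constant" weight scaling).
    width : state word width in bits (default 16).
    x_min : optional (k,) per-component lower clamp, applied after every
        update (e.g. a membrane lower-bounded at 0 for error-coding
        integrators).  ``None`` means the saturation bound.
    comparator : optional :class:`Comparator`.
    """

    k: int
    A_sign: np.ndarray
    A_exp: np.ndarray
    b: np.ndarray
    theta: np.ndarray
    reset_enable: np.ndarray
    Xr: np.ndarray
    noise_exp: np.ndarray | None = None
    refractory_period: int = 0
    modulator_index: int = 0
    syn_gain_exp: np.ndarray | None = None
    width: int = DEFAULT_WIDTH
    x_min: np.ndarray | None = None
    comparator: Comparator | None = None
    name: str = ""

    def __post_init__(self) -> None:
        k = self.k
        if not 1 <= k <= MAX_K:
            raise ConfigError(f"k must be in [1, {MAX_K}], got {k}")
        self.A_sign = np.asarray(self.A_sign, dtype=np.int8)
        self.A_exp = np.asarray(self.A_exp, dtype=np.int8)
        for nm in ("A_sign", "A_exp"):
            arr = getattr(self, nm)
            if arr.shape != (k, k):
                raise ConfigError(f"{nm} must be ({k}, {k}), got {arr.shape}")
        if np.any(np.abs(self.A_exp) > MAX_EXP):
            raise ConfigError(f"|A exponents| must be <= {MAX_EXP}")
        if not np.all(np.isin(self.A_sign, (-1, 0, 1))):
            raise ConfigError("A signs must be in {-1, 0, +1}")
        self.b = np.asarray(self.b, dtype=np.int64)
        self.theta = np.asarray(self.theta, dtype=np.int64)
        self.Xr = np.asarray(self.Xr, dtype=np.int64)
        self.reset_enable = np.asarray(self.reset_enable, dtype=bool)
        if self.noise_exp is None:
            self.noise_exp = np.full(k, NOISE_OFF, dtype=np.int64)
        self.noise_exp = np.asarray(self.noise_exp, dtype=np.int64)
        if self.syn_gain_exp is None:
            self.syn_gain_exp = np.zeros(k, dtype=np.int64)
        self.syn_gain_exp = np.asarray(self.syn_gain_exp, dtype=np.int64)
        for nm in ("b", "theta", "Xr", "reset_enable", "noise_exp", "syn_gain_exp"):
            if getattr(self, nm).shape != (k,):
                raise ConfigError(f"{nm} must have shape ({k},)")
        lo, hi = fxp.sat_bounds(self.width)
        for nm in ("b", "theta", "Xr"):
            arr = getattr(self, nm)
            if np.any((arr < lo) | (arr > hi)):
                raise ConfigError(f"{nm} outside {self.width}-bit state range")
        if self.refractory_period < 0:
            raise ConfigError("refractory_period must be >= 0")
        if not 0 <= self.modulator_index < k:
            raise ConfigError("modulator_index must be < k")
        if self.x_min is not None:
            self.x_min = np.asarray(self.x_min, dtype=np.int64)
            if self.x_min.shape != (k,):
                raise ConfigError(f"x_min must have shape ({k},)")
        c = self.comparator
        if c is not None:
            for idx in (c.target, c.source):
                if not 0 <= idx < k:
                    raise ConfigError("comparator component out of range")

    @staticmethod
    def diag_leak(k: int, exponents, signs=None, **kw) -> "NeuronParamGroup":
        """Convenience constructor: diagonal transition matrix (pure leaks)."""
        exponents = np.atleast_1d(exponents)
        A_sign = np.zeros((k, k), dtype=np.int8)
        A_exp = np.zeros((k, k), dtype=np.int8)
        signs = np.full(k, -1) if signs is None else np.atleast_1d(signs)
        for i in range(k):
            A_sign[i, i] = signs[i]
            A_exp[i, i] = exponents[i] if exponents.size > 1 else exponents[0]
        kw.setdefault("b", np.zeros(k, dtype=np.int64))
        kw.setdefault("theta", np.full(k, fxp.sat_bounds(kw.get("width", DEFAULT_WIDTH))[1]))
        kw.setdefault("reset_enable", np.zeros(k, dtype=bool))
        kw.setdefault("Xr", np.zeros(k, dtype=np.int64))
        return NeuronParamGroup(k=k, A_sign=A_sign, A_exp=A_exp, **kw)


class GroupState:
    """State of one neuron group inside the global state arrays.

    The group owns the slice ``[start, start + n)`` of the network-level
    state matrix; all stage-1 work happens on that slice.
    """

    def __init__(self, params: NeuronParamGroup, start: int, n: int, core: int = 0):
        self.params = params
        self.start = start
        self.n = n
        self.core = core
        self.sl = slice(start, start + n)

    # -- stage 1 ------------------------------------------------------------
    def stage1_integrate(self, x: np.ndarray, acc: np.ndarray, refr: np.ndarray,
                         gids: np.ndarray, tick: int, seed: int,
                         bias_extra: np.ndarray | None = None) -> None:
        """x[t+1] = sat(x + A<>x + acc + noise + b) on this group's slice;
        refractory neurons keep component 0 clamped at the reset value.
        ``bias_extra`` is an optional network-level per-neuron drive added
        alongside the group bias (clamping currents, per-unit offsets)."""
        p = self.params
        k = p.k
        xg = x[self.sl, :k]
        inc = acc[self.sl, :k].astype(np.int64)
        inc += p.b
        if bias_extra is not None:
            inc += bias_extra[self.sl, :k]
        for i in range(k):
            for j in range(k):
                s = int(p.A_sign[i, j])
                if s == 0:
                    continue
                inc[:, i] += fxp.leak_apply_vec(s, int(p.A_exp[i, j]), xg[:, j], p.width)
            ne = int(p.noise_exp[i])
            if ne != NOISE_OFF:
                inc[:, i] += fxp.draw_noise_vec(ne, seed, gids[self.sl], tick, lane=i)
        new = xg.astype(np.int64) + inc
        lo, hi = fxp.sat_bounds(p.width)
        np.clip(new, lo, hi, out=new)
        if p.x_min is not None:
            np.maximum(new, p.x_min, out=new)
        x[self.sl, :k] = new
        # refractory clamp: hold component 0 at reset, decrement counters
        rg = refr[self.sl]
        clamped = rg > 0
        if clamped.any():
            xs = x[self.sl]
            xs[clamped, 0] = p.Xr[0]
            x[self.sl] = xs
            refr[self.sl] = rg - clamped
        c = p.comparator
        if c is not None:
            src = x[self.sl, c.source]
            x[self.sl, c.target] = np.where(src >= c.threshold, c.value_ge, c.value_lt)

    # -- spike / reset ------------------------------------------------------
    def apply_thresholds(self, x: np.ndarray, refr: np.ndarray) -> np.ndarray:
        """Per-component conditional resets plus spike detection on
        component 0.  Returns the *local* indices of spiking neurons."""
        p = self.params
        spikes = (x[self.sl, 0] >= p.theta[0]) & (refr[self.sl] == 0)
        for i in range(p.k):
            if p.reset_enable[i]:
                over = x[self.sl, i] >= p.theta[i]
                if i == 0:
                    over &= spikes  # refractory neurons stay clamped
                if over.any():
                    col = x[self.sl, i]
                    col[over] = p.Xr[i]
                    x[self.sl, i] = col
        if p.refractory_period > 0 and spikes.any():
            rg = refr[self.sl]
            rg[spikes] = p.refractory_period
            refr[self.sl] = rg
        return np.nonzero(spikes)[0]


def shift_mult_varexp(exp: np.ndarray, x: np.ndarray, width: int = 32) -> np.ndarray:
    """Elementwise ``x * 2**exp`` with per-element exponents (truncating
    toward zero on down-shifts, saturating on up-shifts)."""
    exp = np.asarray(exp, dtype=np.int64)
    x = np.asarray(x, dtype=np.int64)
    up = np.clip(exp, 0, None)
    down = np.clip(-exp, 0, None)
    out = np.sign(x) * (np.abs(x) >> down)
    out = fxp.saturate(out << up, width)
    return out
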