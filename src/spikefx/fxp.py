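"""Fixed-point, multiplier-less arithmetic primitives.

Every multiplicative coefficient in the simulator is a signed power of two,
so the only arithmetic needed is addition, comparison and bit shifting.
This module provides:

* :func:`shift_mult` -- the corrected signed shift ``a diamond x = x * 2**a``
  with truncation toward zero.  A plain arithmetic right shift of a negative
  two's-complement integer rounds toward minus infinity (``-4 >> 3 == -1``),
  which would make small negative states never decay to zero.  The corrected
  shift returns 0 in that case.
* :func:`leak_apply` -- the leak increment a transition-matrix entry
  contributes to a state, with a guaranteed minimum one-LSB decay toward
  rest so that states cannot stall at small nonzero values.
* :func:`randomized_round` -- unbiased stochastic rounding of weight
  updates: the ``r`` low bits of the update are interpreted as the
  probability of incrementing the truncated magnitude.
* :func:`draw_noise` / :func:`blankout_mask` -- keyed integer noise and
  Bernoulli draws.

All randomness is counter-based: a draw is a pure function of a
:class:`RngStreamKey` (seed, neuron, tick, purpose), so simulations are
reproducible and independent of how neurons are partitioned across cores.
Scalar wrappers exist for clarity and testing; the ``*_vec`` variants are
the ones used in the simulation hot path.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_WIDTH",
    "Purpose",
    "RngStreamKey",
    "ShiftCoeff",
    "sat_bounds",
    "saturate",
    "shift_mult",
    "shift_mult_vec",
    "leak_apply",
    "leak_apply_vec",
    "randomized_round",
    "randomized_round_vec",
    "draw_noise",
    "draw_noise_vec",
    "blankout_mask",
    "blankout_mask_vec",
    "uniform_bits",
]

DEFAULT_WIDTH = 16
MAX_EXP = 15

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)


class Purpose(enum.IntEnum):
    """Tag separating independent random streams drawn at the same tick."""

    NOISE = 1
    BLANKOUT = 2
    ROUNDING = 3


@dataclass(frozen=True)
class RngStreamKey:
    """Counter-based key: the triple uniquely determines the random draw."""

    seed: int
    neuron: int
    tick: int
    purpose: Purpose = Purpose.NOISE


@dataclass(frozen=True)
class ShiftCoeff:
    """A signed power-of-two coefficient: ``sign * 2**exponent``.

    ``sign == 0`` is the exact-zero sentinel (the exponent is ignored).
    """

    sign: int
    exponent: int = 0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign}")
        if abs(self.exponent) > MAX_EXP:
            raise ValueError(f"|exponent| must be <= {MAX_EXP}, got {self.exponent}")

    @property
    def value(self) -> float:
        return 0.0 if self.sign == 0 else self.sign * 2.0**self.exponent

    @classmethod
    def from_float(cls, v: float, max_exp: int = MAX_EXP) -> "ShiftCoeff":
        """Nearest signed power of two (geometric rounding); 0 maps to the sentinel."""
        if v == 0:
            return cls(0, 0)
        e = int(np.clip(np.round(np.log2(abs(v))), -max_exp, max_exp))
        return cls(1 if v > 0 else -1, e)


def sat_bounds(width: int = DEFAULT_WIDTH) -> tuple[int, int]:
    """(lo, hi) of a signed integer of ``width`` bits."""
    return -(1 << (width - 1)), (1 << (width - 1)) - 1


def saturate(x, width: int = DEFAULT_WIDTH):
    """Clip to the signed range of ``width`` bits (never wraps)."""
    lo, hi = sat_bounds(width)
    if np.isscalar(x):
        return int(min(max(x, lo), hi))
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# corrected signed shift
# ---------------------------------------------------------------------------

def shift_mult(exponent: int, x: int, width: int = DEFAULT_WIDTH) -> int:
    """``x * 2**exponent`` with truncation toward zero and saturating up-shift.

    The first argument is always the shift exponent.  Down-shifts compute
    ``sign(x) * (|x| >> -exponent)``, so ``shift_mult(-a, -2**ap) == 0``
    for every ``ap < a`` -- unlike the plain arithmetic right shift, which
    yields -1 for any negative input of small magnitude.
    """
    if abs(exponent) > MAX_EXP:
        raise ValueError(f"|exponent| must be <= {MAX_EXP}")
    x = int(x)
    if exponent >= 0:
        return saturate(x << exponent, width)
    mag = abs(x) >> -exponent
    return -mag if x < 0 else mag


def shift_mult_vec(exponent: int, x: np.ndarray, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Vectorized :func:`shift_mult` (single exponent, array of states)."""
    x = np.asarray(x)
    if exponent >= 0:
        return saturate(x.astype(np.int64) << exponent, width)
    return np.sign(x) * (np.abs(x) >> -exponent)


# ---------------------------------------------------------------------------
# leak operator
# ---------------------------------------------------------------------------

def leak_apply(coeff: ShiftCoeff, x: int, width: int = DEFAULT_WIDTH) -> int:
    """Increment the transition-matrix entry ``coeff`` contributes for state ``x``.

    ``sign(coeff) * shift_mult(coeff.exponent, x)``, except that a
    negative-signed (leak) contribution whose shifted magnitude truncates
    to zero returns ``-sign(x)``: a minimum one-LSB decay toward rest, so
    that a pure leak always reaches exactly zero from either polarity.
    """
    if coeff.sign == 0:
        return 0
    shifted = shift_mult(coeff.exponent, x, width)
    out = coeff.sign * shifted
    if coeff.sign == -1 and shifted == 0 and x != 0:
        return -1 if x > 0 else 1
    return out


def leak_apply_vec(sign: int, exponent: int, x: np.ndarray, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Vectorized :func:`leak_apply` for one coefficient over many states."""
    if sign == 0:
        return np.zeros_like(np.asarray(x), dtype=np.int64)
    shifted = shift_mult_vec(exponent, x, width).astype(np.int64)
    out = sign * shifted
    if sign < 0:
        # leak whose shifted magnitude truncated to zero: one-LSB decay
        stall = (shifted == 0) & (x != 0)
        out = np.where(stall, -np.sign(x), out)
    return out


# ---------------------------------------------------------------------------
# counter-based uniform bits (splitmix64 finalizer chain)
# ---------------------------------------------------------------------------

_GOLDEN = _U64(0x9E3779B97F4A7C15)
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)


def _mix(z):
    z = (z + _GOLDEN) & _MASK64
    z = ((z ^ (z >> _U64(30))) * _M1) & _MASK64
    z = ((z ^ (z >> _U64(27))) * _M2) & _MASK64
    return z ^ (z >> _U64(31))


def _mix_scalar(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def uniform_bits(seed: int, neuron, tick: int, purpose: int, lane: int = 0):
    """64 uniform bits, a pure function of (seed, neuron, tick, purpose, lane).

    ``neuron`` may be a scalar or an integer array; the result has the same
    shape.  ``lane`` separates multiple draws needed for one purpose.  The
    scalar part of the key (seed, tick, purpose, lane) is pre-mixed in
    plain Python; only two finalizer rounds run over the array.
    """
    h0 = _mix_scalar(_mix_scalar(seed & 0xFFFFFFFFFFFFFFFF)
                     ^ (tick & 0xFFFFFFFFFFFFFFFF))
    h0 = _mix_scalar(h0 ^ ((purpose & 0xFF) << 8 | (lane & 0xFF)))
    with np.errstate(over="ignore"):
        n = np.asarray(neuron, dtype=np.uint64)
        return _mix(_mix(_U64(h0) ^ n))


def _uniform_below(bits, modulus_exp: int):
    """Uniform integer in [0, 2**modulus_exp) from 64 uniform bits."""
    return (bits >> _U64(64 - modulus_exp)).astype(np.int64)


# ---------------------------------------------------------------------------
# randomized rounding
# ---------------------------------------------------------------------------

def randomized_round(delta: int, r: int, key: RngStreamKey) -> int:
    """Unbiased stochastic rounding: drop the ``r`` low bits of ``|delta|`` and
    increment with probability (low bits)/2**r; the sign is re-applied.
    ``E[out] * 2**r == delta`` exactly.
    """
    out = randomized_round_vec(
        np.array([delta], dtype=np.int64), r, key.seed,
        np.array([key.neuron], dtype=np.int64), key.tick,
    )
    return int(out[0])


def randomized_round_vec(delta: np.ndarray, r: int, seed: int, keys: np.ndarray,
                         tick: int, lane: int = 0) -> np.ndarray:
    """Vectorized randomized rounding; ``keys`` identifies each draw (e.g. a
    synapse index), paired with (seed, tick, purpose=ROUNDING, lane)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    delta = np.asarray(delta, dtype=np.int64)
    if r == 0:
        return delta.copy()
    mag = np.abs(delta)
    base = mag >> r
    p = mag & ((1 << r) - 1)
    bits = uniform_bits(seed, keys, tick, Purpose.ROUNDING, lane)
    draw = _uniform_below(bits, r)
    out = base + (draw < p)
    return np.sign(delta) * out


# ---------------------------------------------------------------------------
# integer noise
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _noise_halfwidth(variance_exponent: int) -> int:
    """Half-width M of the four summed uniforms on [-M, M] whose total
    variance 4*M*(M+1)/3 is closest to 2**variance_exponent."""
    target = 2.0**variance_exponent
    m = int(round((np.sqrt(3.0 * target + 1.0) - 1.0) / 2.0))
    best, best_err = 1, float("inf")
    for cand in (m - 1, m, m + 1):
        if cand < 1:
            continue
        err = abs(4.0 * cand * (cand + 1) / 3.0 - target)
        if err < best_err:
            best, best_err = cand, err
    return best


def draw_noise(variance_exponent: int, key: RngStreamKey) -> int:
    """Zero-mean integer noise of variance ~2**variance_exponent, from the
    sum of four independent uniform draws (approximately normal)."""
    out = draw_noise_vec(variance_exponent, key.seed,
                         np.array([key.neuron], dtype=np.int64), key.tick)
    return int(out[0])

def draw_noise_vec(variance_exponent: int, seed: int, neurons: np.ndarray,
                   tick: int, lane: int = 0) -> np.ndarray:
    m = _noise_halfwidth(variance_exponent)
    span = 2 * m + 1
    # the four summed uniforms ride on sub-lane-tagged copies of the keys,
    # drawn in a single batch
    n = np.asarray(neurons, dtype=np.uint64)
    with np.errstate(over="ignore"):
        tagged = (n[None, :] + (np.arange(4, dtype=np.uint64)[:, None]
                                << np.uint64(48)))
    bits = uniform_bits(seed, tagged, tick, Purpose.NOISE, lane)
    # uniform on [0, span) via 32-bit multiply-shift, then center
    u = ((bits >> _U64(32)) * _U64(span)) >> _U64(32)
    return (u.astype(np.int64) - m).sum(axis=0)


# ---------------------------------------------------------------------------
# blank-out Bernoulli mask
# ---------------------------------------------------------------------------

def blankout_mask(p_num: int, p_den_exponent: int, key: RngStreamKey) -> int:
    """1 with probability p_num / 2**p_den_exponent, else 0."""
    out = blankout_mask_vec(p_num, p_den_exponent, key.seed,
                            np.array([key.neuron], dtype=np.int64), key.tick)
    return int(out[0])


def blankout_mask_vec(p_num: int, p_den_exponent: int, seed: int,
                      keys: np.ndarray, tick: int, lane: int = 0) -> np.ndarray:
    if not (0 <= p_num <= (1 << p_den_exponent)):
        raise ValueError("p_num must lie in [0, 2**p_den_exponent]")
    if p_num == (1 << p_den_exponent):
        return np.ones(np.shape(keys), dtype=np.int64)
    if p_num == 0:
        return np.zeros(np.shape(keys), dtype=np.int64)
    bits = uniform_bits(seed, keys, tick, Purpose.BLANKOUT, lane)
    draw = _uniform_below(bits, p_den_exponent)
    return (draw < p_num).astype(np.int64)
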