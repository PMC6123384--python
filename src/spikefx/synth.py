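"""Deterministic synthetic input generators.

All generators are pure functions of (spec, seed): regeneration is
bit-identical, using the same counter-based bit source as the simulator,
so no fixture files are needed.  Spike trains use a Bernoulli-per-tick
approximation of a Poisson process (with 1 tick = 1 ms, the per-tick spike
probability is rate/1000; exact to within ~2% at the firing rates used
here).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from . import fxp

__all__ = ["SpikeTrainSpec", "poisson_trains", "bars_stripes",
           "embedded_pattern_trains", "load_idx"]

_GEN_PURPOSE = 7  # random-stream tag for synthetic inputs


@dataclass(frozen=True)
class SpikeTrainSpec:
    """Rate schedule for a bank of Poisson channels.

    ``schedule`` is a list of ``(t0, t1, c0, c1, rate_hz)`` entries: channels
    ``[c0, c1)`` fire at ``rate_hz`` during ticks ``[t0, t1)``.  Entries may
    not overlap on the same channel.
    """

    n_channels: int
    schedule: tuple = ()

    def __post_init__(self):
        for (t0, t1, c0, c1, rate) in self.schedule:
            if rate < 0:
                raise ValueError("rates must be >= 0")
            if not (0 <= c0 <= c1 <= self.n_channels):
                raise ValueError("channel range out of bounds")


def _bernoulli_block(seed: int, t0: int, t1: int, channels: np.ndarray,
                     rate_hz: float, stream: int = 0) -> np.ndarray:
    """(tick, channel) events from per-tick Bernoulli draws, p = rate/1000."""
    if rate_hz <= 0 or t1 <= t0 or len(channels) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    p64 = int(min(rate_hz / 1000.0, 1.0) * 2.0**64)
    out_t, out_c = [], []
    for t in range(t0, t1):
        bits = fxp.uniform_bits(seed, channels, t, _GEN_PURPOSE, lane=stream)
        hit = bits.astype(np.float64) < p64  # compare via float to avoid u64 literals
        if hit.any():
            out_t.append(np.full(hit.sum(), t, dtype=np.int64))
            out_c.append(channels[hit])
    if not out_t:
        return np.zeros((0, 2), dtype=np.int64)
    return np.column_stack([np.concatenate(out_t), np.concatenate(out_c)])


def poisson_trains(spec: SpikeTrainSpec, seed: int) -> np.ndarray:
    """Events (tick, channel) for the whole schedule, sorted by tick."""
    blocks = [
        _bernoulli_block(seed, t0, t1, np.arange(c0, c1, dtype=np.int64), rate)
        for (t0, t1, c0, c1, rate) in spec.schedule
    ]
    ev = (np.vstack(blocks) if blocks else np.zeros((0, 2), dtype=np.int64))
    order = np.lexsort((ev[:, 1], ev[:, 0]))
    return ev[order]


def bars_stripes() -> tuple[np.ndarray, np.ndarray]:
    """The 32 labelled 4x4 bars-and-stripes patterns.

    Returns (patterns, labels): patterns is (32, 4, 4) binary; the first 16
    are the row-generated ("bars", label 0) patterns ordered by the binary
    code of their row mask, the next 16 column-generated ("stripes", label
    1).  The all-off and all-on patterns appear once in each class.
    """
    pats, labels = [], []
    for code in range(16):
        rows = np.array([(code >> i) & 1 for i in range(4)], dtype=np.int64)
        pats.append(np.repeat(rows[:, None], 4, axis=1))
        labels.append(0)
    for code in range(16):
        cols = np.array([(code >> i) & 1 for i in range(4)], dtype=np.int64)
        pats.append(np.repeat(cols[None, :], 4, axis=0))
        labels.append(1)
    return np.array(pats), np.array(labels)


def embedded_pattern_trains(n_inputs: int = 100, pattern_len: int = 50,
                            n_repeats: int = 20, noise_len: int = 50,
                            rate_hz: float = 20.0, seed: int = 0,
                            ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Alternating noise / frozen-pattern spike segments at matched rate.

    A fixed random spike pattern of ``pattern_len`` ticks is generated once
    and re-presented ``n_repeats`` times, interleaved with fresh random
    segments of the same firing rate.  Returns (events, windows) where
    ``windows`` lists the [start, end) tick range of every pattern
    presentation.
    """
    channels = np.arange(n_inputs, dtype=np.int64)
    pattern = _bernoulli_block(seed, 0, pattern_len, channels, rate_hz, stream=1)
    events, windows = [], []
    t = 0
    for rep in range(n_repeats):
        noise = _bernoulli_block(seed, t, t + noise_len, channels, rate_hz)
        events.append(noise)
        t += noise_len
        shifted = pattern.copy()
        shifted[:, 0] += t
        events.append(shifted)
        windows.append((t, t + pattern_len))
        t += pattern_len
    tail = _bernoulli_block(seed, t, t + noise_len, channels, rate_hz)
    events.append(tail)
    ev = np.vstack(events)
    order = np.lexsort((ev[:, 1], ev[:, 0]))
    return ev[order], windows


def load_idx(images_path: str, labels_path: str | None = None,
             max_rate_hz: float = 250.0):
    """Read IDX-format images (optionally labels) and scale pixel
    intensities to per-pixel Poisson rates in Hz.

    Only needed for the full-scale digit-classification demo; never used
    by the test-suite.
    """
    with open(images_path, "rb") as f:
        magic, = struct.unpack(">I", f.read(4))
        if magic != 0x00000803:
            raise IOError(f"{images_path}: bad IDX magic {magic:#010x}")
        n, rows, cols = struct.unpack(">III", f.read(12))
        data = np.frombuffer(f.read(n * rows * cols), dtype=np.uint8)
        if data.size != n * rows * cols:
            raise IOError(f"{images_path}: truncated IDX payload")
        rates = data.reshape(n, rows * cols).astype(np.float64) / 255.0 * max_rate_hz
    labels = None
    if labels_path is not None:
        with open(labels_path, "rb") as f:
            magic, = struct.unpack(">I", f.read(4))
            if magic != 0x00000801:
                raise IOError(f"{labels_path}: bad IDX magic {magic:#010x}")
            m, = struct.unpack(">I", f.read(4))
            labels = np.frombuffer(f.read(m), dtype=np.uint8).astype(np.int64)
            if labels.size != m:
                raise IOError(f"{labels_path}: truncated IDX payload")
    return rates, labels
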