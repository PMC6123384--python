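"""Three-factor, event-driven, forward-table nearest-neighbor STDP engine.

The engine is *pre-sensitive*: every weight update -- causal (post fires
after pre, potentiation side) and acausal (post fired before pre) -- is
triggered by a pre-synaptic event or by the expiry of the pre-synaptic
neuron's timer, so only forward rows of the synapse table are ever read.
Per-neuron timer state is O(N) in the number of neurons, independent of
the synapse count.

Scheme, for a pre-synaptic spike at tick ``p`` arriving at its synapses:

1. If the pre neuron's previous spike ``p0`` still has a pending causal
   window, commit the causal update first: the *earliest* post spike in
   ``[p0, p-1]`` within the causal window pairs with ``p0``.
2. Acausal pass: each post target whose most recent spike lies in
   ``[p - T_ac, p - 1]`` receives an acausal update.
3. The pre timer restarts; if no further pre spike arrives, the causal
   window of ``p`` is committed when the timer expires at ``p + T_ca``.

A post spike at the same tick as a pre spike (lag 0) is paired causally
(causal wins ties).  Each update is the kernel's log-scale amplitude
applied, as a bit shift, to the post neuron's modulator state component
``x_m`` -- the third factor -- optionally gated by a boxcar on another
state component, then randomized-rounded into the low-precision weight
and clipped to the weight range.

The nearest-neighbor pairing needs the earliest post spike inside a
window, which a single last-spike value cannot provide when several post
spikes fall inside one causal window; each neuron therefore keeps a short
ring of recent spike ticks (still O(N) memory).  With refractory periods
at least as long as the STDP window -- the regime in which this scheme
equals exact nearest-neighbor STDP -- a single entry is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fxp
from .dynamics import shift_mult_varexp

__all__ = ["STDPKernelConfig", "PlasticityConfig", "PlasticityEngine",
           "nearest_neighbor_stdp_oracle"]

LONG_AGO = -(1 << 60)
HISTORY = 8  # per-neuron spike-history ring length


@dataclass(frozen=True)
class STDPKernelConfig:
    """Multiplier-free STDP window: a staircase of shift exponents.

    ``mode='exp'`` approximates an exponential window: the amplitude
    exponent starts at ``ca_exp`` (resp. ``ac_exp``) at lag 0 and is
    decremented by one every ``half_decay`` ticks, i.e. K(dt) ~ 2**(K0 -
    dt/half_decay).  ``mode='linear'`` uses explicit breakpoints: a list of
    ``(start_lag, exponent)`` pairs defining a piecewise-constant exponent
    staircase.  The kernel is exactly zero outside ``[-t_ac, t_ca]``.
    """

    t_ca: int = 32
    t_ac: int = 32
    ca_exp: int = 0
    ac_exp: int = 0
    ca_sign: int = 1
    ac_sign: int = -1
    mode: str = "exp"
    half_decay: int = 16
    breakpoints_ca: tuple = ()
    breakpoints_ac: tuple = ()

    def __post_init__(self):
        if self.t_ca < 1 or self.t_ac < 1:
            raise ValueError("STDP windows must be >= 1 tick")
        if self.mode not in ("exp", "linear"):
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        if self.mode == "exp" and self.half_decay < 1:
            raise ValueError("half_decay must be >= 1 tick")

    def _staircase(self, amp_exp: int, window: int, breakpoints) -> np.ndarray:
        exps = np.full(window + 1, amp_exp, dtype=np.int64)
        if self.mode == "exp":
            lags = np.arange(window + 1)
            exps = amp_exp - lags // self.half_decay
        else:
            for start, e in sorted(breakpoints):
                exps[start:] = e
        return exps

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(causal, acausal) exponent tables indexed by |lag|."""
        return (self._staircase(self.ca_exp, self.t_ca, self.breakpoints_ca),
                self._staircase(self.ac_exp, self.t_ac, self.breakpoints_ac))

    def eval(self, dt: int) -> tuple[int, int] | None:
        """Kernel (sign, shift exponent) at signed lag ``dt`` (positive =
        causal, post after pre); ``None`` outside the window."""
        ca, ac = self.tables()
        if 0 <= dt <= self.t_ca:
            return self.ca_sign, int(ca[dt])
        if -self.t_ac <= dt < 0:
            return self.ac_sign, int(ac[-dt])
        return None


@dataclass(frozen=True)
class PlasticityConfig:
    """One learning rule shared by a set of synapses.

    ``state_driven=True`` replaces timing-dependent STDP with a purely
    state-dependent update (the acausal pipeline alone): every pre-synaptic
    spike commits ``ca_sign * (x_m >> -ca_exp)`` regardless of post spike
    timing -- the form taken by error-modulated (eRBP) and voltage/calcium
    sequence-learning rules.

    ``modulation_mode`` fixes the operand order of the shift between the
    kernel and the modulator: the default ``'mod-by-kernel'`` shifts the
    modulator state by the kernel exponent (update linear in ``x_m``,
    logarithmic in the kernel); ``'kernel-by-mod'`` shifts the kernel
    amplitude by the modulator value interpreted as an exponent.

    ``update_on_dropped=True`` lets weight updates proceed even when the
    blank-out mask dropped the spike at the synapse (synaptic-sampling
    mode); otherwise plasticity sees only delivered (post-mask) spikes.
    """

    kernel: STDPKernelConfig = field(default_factory=STDPKernelConfig)
    w_min: int = -128
    w_max: int = 127
    r: int = 0
    mod_idx: int = 0
    modulation_mode: str = "mod-by-kernel"
    gate_comp: int | None = None
    gate_min: int = 0
    gate_max: int = 0
    update_on_dropped: bool = True
    state_driven: bool = False

    def __post_init__(self):
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.r < 0:
            raise ValueError("rounding bits r must be >= 0")
        if self.modulation_mode not in ("mod-by-kernel", "kernel-by-mod"):
            raise ValueError(f"unknown modulation_mode {self.modulation_mode!r}")


class PlasticityEngine:
    """Event-driven plasticity over a finalized network's synapse arrays.

    Built by :class:`~spikefx.network.Network`; operates in place on the
    shared weight pool.  All randomness (blank-out replay, randomized
    rounding) is counter-based on (seed, synapse id, tick).
    """

    def __init__(self, net, configs: list[PlasticityConfig]):
        self.net = net
        self.configs = configs
        self.tables = [cfg.kernel.tables() for cfg in configs]
        n = net.n_neurons
        self.hist = np.full((n, HISTORY), LONG_AGO, dtype=np.int64)
        self.hist_pos = np.zeros(n, dtype=np.int64)
        self.last_pre = np.full(n, LONG_AGO, dtype=np.int64)
        self.pending = np.zeros(n, dtype=bool)
        self.expiry: dict[int, list[int]] = {}
        # forward rows restricted to plastic synapses, grouped by config
        self.rows: dict[int, list[tuple[int, np.ndarray]]] = {}
        plastic = np.nonzero(net.syn_plast >= 0)[0]
        for idx in plastic:
            pre = int(net.syn_pre[idx])
            self.rows.setdefault(pre, [])
        for pre in self.rows:
            lo, hi = net.row_ptr[pre], net.row_ptr[pre + 1]
            sel = np.arange(lo, hi)[net.syn_plast[lo:hi] >= 0]
            for cid in np.unique(net.syn_plast[sel]):
                self.rows[pre].append((int(cid), sel[net.syn_plast[sel] == cid]))
        self.max_tca = {pre: max(self.configs[cid].kernel.t_ca
                                 for cid, _ in groups)
                        for pre, groups in self.rows.items()}
        self.row_accesses: list[int] = []  # instrumentation: pre rows touched

    # ------------------------------------------------------------------
    def register_post_spikes(self, gids: np.ndarray, tick: int) -> None:
        if len(gids) == 0:
            return
        self.hist[gids, self.hist_pos[gids] % HISTORY] = tick
        self.hist_pos[gids] += 1

    # ------------------------------------------------------------------
    def _commit(self, cfg_id: int, idxs: np.ndarray, lags: np.ndarray,
                causal: bool, tick: int, lane: int, emission: int) -> None:
        """Turn kernel lags into modulated, rounded, clipped weight changes."""
        cfg = self.configs[cfg_id]
        net = self.net
        if not cfg.update_on_dropped:
            mask = net._blankout_for(idxs, emission)
            idxs, lags = idxs[mask], lags[mask]
        if len(idxs) == 0:
            return
        ca_tab, ac_tab = self.tables[cfg_id]
        if cfg.state_driven:
            sign = cfg.kernel.ca_sign
            exps = np.full(len(idxs), cfg.kernel.ca_exp, dtype=np.int64)
        elif causal:
            sign = cfg.kernel.ca_sign
            exps = ca_tab[lags]
        else:
            sign = cfg.kernel.ac_sign
            exps = ac_tab[lags]
        posts = net.syn_post[idxs]
        xm = net.x[posts, cfg.mod_idx].astype(np.int64)
        if cfg.modulation_mode == "mod-by-kernel":
            delta = sign * shift_mult_varexp(exps, xm)
        else:
            amp = sign * (np.int64(1) << np.clip(exps, 0, None))
            delta = shift_mult_varexp(np.clip(xm, -fxp.MAX_EXP, fxp.MAX_EXP), amp)
        if cfg.gate_comp is not None:
            g = net.x[posts, cfg.gate_comp]
            delta = np.where((g >= cfg.gate_min) & (g <= cfg.gate_max), delta, 0)
        live = delta != 0
        if not live.all():
            idxs, delta = idxs[live], delta[live]
        if len(idxs) == 0:
            return
        rounded = fxp.randomized_round_vec(delta, cfg.r, net.seed,
                                           net.syn_id[idxs], tick, lane=lane)
        slots = net.syn_slot[idxs]
        np.add.at(net.weights, slots, rounded)
        net.weights[slots] = np.clip(net.weights[slots], cfg.w_min, cfg.w_max)

    # ------------------------------------------------------------------
    def _earliest_in(self, posts: np.ndarray, start: int, end: int):
        """Per post, earliest recorded spike tick in [start, end] (LONG_AGO
        if none)."""
        h = self.hist[posts]  # (m, HISTORY)
        ok = (h >= start) & (h <= end)
        h = np.where(ok, h, np.int64(1) << 62)
        earliest = h.min(axis=1)
        return np.where(earliest == np.int64(1) << 62, LONG_AGO, earliest)

    def _latest_in(self, posts: np.ndarray, start: int, end: int):
        h = self.hist[posts]
        ok = (h >= start) & (h <= end)
        h = np.where(ok, h, LONG_AGO)
        return h.max(axis=1)

    # ------------------------------------------------------------------
    def _commit_causal_window(self, pre: int, p0: int, end: int, tick: int) -> None:
        for cid, idxs in self.rows[pre]:
            cfg = self.configs[cid]
            if cfg.state_driven:
                continue
            hi = min(end, p0 + cfg.kernel.t_ca)
            posts = self.net.syn_post[idxs]
            tpost = self._earliest_in(posts, p0, hi)
            hit = tpost != LONG_AGO
            if hit.any():
                self._commit(cid, idxs[hit], (tpost[hit] - p0), True,
                             tick, lane=0, emission=p0)

    def on_pre_event(self, pre: int, emission: int, tick: int) -> None:
        """Pre-synaptic spike emitted at ``emission``, processed at stage 2
        of ``tick`` (= emission + 1)."""
        if pre not in self.rows:
            return
        self.row_accesses.append(pre)
        if self.pending[pre]:
            self._commit_causal_window(pre, int(self.last_pre[pre]),
                                       emission - 1, tick)
        for cid, idxs in self.rows[pre]:
            cfg = self.configs[cid]
            if cfg.state_driven:
                lags = np.zeros(len(idxs), dtype=np.int64)
                self._commit(cid, idxs, lags, False, tick, lane=2,
                             emission=emission)
                continue
            posts = self.net.syn_post[idxs]
            tpost = self._latest_in(posts, emission - cfg.kernel.t_ac,
                                    emission - 1)
            hit = tpost != LONG_AGO
            if hit.any():
                self._commit(cid, idxs[hit], (emission - tpost[hit]), False,
                             tick, lane=1, emission=emission)
        if any(not self.configs[cid].state_driven for cid, _ in self.rows[pre]):
            self.last_pre[pre] = emission
            self.pending[pre] = True
            self.expiry.setdefault(emission + self.max_tca[pre] + 1, []).append(pre)

    def on_expiries(self, tick: int) -> None:
        """Commit causal windows of timers expiring at this tick."""
        for pre in self.expiry.pop(tick, ()):  # scheduled at spike time
            p0 = tick - 1 - self.max_tca[pre]
            if self.pending[pre] and self.last_pre[pre] == p0:
                self.row_accesses.append(pre)
                self._commit_causal_window(pre, p0, p0 + self.max_tca[pre], tick)
                self.pending[pre] = False


# ---------------------------------------------------------------------------
# independent oracle used by the test-suite
# ---------------------------------------------------------------------------

def nearest_neighbor_stdp_oracle(pre_ticks, post_ticks, kernel: STDPKernelConfig,
                                 modulator: int) -> int:
    """Brute-force nearest-neighbor STDP total weight change from a complete
    spike record (no rounding, frozen modulator, no clipping).

    Each pre spike pairs acausally with the nearest post spike strictly
    before it, and causally with the nearest post spike at-or-after it
    (causal wins lag-0 ties); lags outside the kernel windows contribute
    nothing.  This matches exact nearest-neighbor STDP whenever refractory
    periods are at least as long as the STDP windows.
    """
    pre_ticks = sorted(int(t) for t in pre_ticks)
    post_ticks = sorted(int(t) for t in post_ticks)
    total = 0
    for n, p in enumerate(pre_ticks):
        nxt = pre_ticks[n + 1] if n + 1 < len(pre_ticks) else None
        # causal: earliest post at-or-after p, before the next pre spike
        after = [t for t in post_ticks if t >= p and (nxt is None or t < nxt)]
        if after and after[0] - p <= kernel.t_ca:
            sign, e = kernel.eval(after[0] - p)
            total += sign * fxp.shift_mult(e, modulator)
        # acausal: latest post strictly before p
        before = [t for t in post_ticks if t < p]
        if before and p - before[-1] <= kernel.t_ac:
            sign, e = kernel.eval(-(p - before[-1]))
            total += sign * fxp.shift_mult(e, modulator)
    return total
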