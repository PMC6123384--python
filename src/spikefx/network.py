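"""Multi-core two-stage tick loop: routing, delays, plasticity, recording.

A :class:`Network` is built from neuron groups (each assigned to a core),
a forward-indexed synapse table and optional plasticity configurations,
then run for a number of ticks.  Every tick executes two stages separated
by barriers:

* **stage 1** -- every core integrates its neuron dynamics (without the
  current tick's synaptic input), detects threshold crossings, applies
  resets and refractory clamps, and emits spike events;
* **routing** -- spike addresses are routed to their destination synapses;
  an event emitted at tick ``t`` with axonal delay ``d`` is delivered at
  tick ``t + 1 + d`` (spikes become available to the *next* tick);
* **stage 2** -- every core accumulates the deliveries due this tick onto
  its state components (through the per-delivery Bernoulli blank-out mask
  and the power-of-two synaptic gain) and runs the plasticity engine.

Cores are simulated sequentially between explicit barrier points.  Because
every random draw is keyed by global neuron/synapse id and tick (never by
core), any assignment of groups to cores produces a bit-identical spike
raster -- the schedule, not threading, defines the semantics.

External input events are injected as spikes of dedicated input neurons:
an event stamped ``t`` is treated as emitted at ``t - 1`` so it obeys the
same one-tick availability rule as internal spikes.

The run record counts SynOps -- synaptic events actually delivered and
accumulated (post blank-out) -- the framework's unit of computational cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fxp
from .dynamics import ConfigError, GroupState, NeuronParamGroup, shift_mult_varexp
from .plasticity import PlasticityConfig, PlasticityEngine

__all__ = ["Network", "SimRecord", "EventPacket", "BL_DEN_EXP"]

BL_DEN_EXP = 8  # blank-out probabilities are p_num / 2**8
ACC_WIDTH = 32  # synaptic accumulator word width (wider than the state)


@dataclass(frozen=True)
class EventPacket:
    """A routed spike: delivery tick = emission + 1 + delay."""

    emission: int
    src: int
    dst: int
    delay: int = 0

    @property
    def delivery(self) -> int:
        return self.emission + 1 + self.delay


@dataclass
class SimRecord:
    """Outcome of a run: spike raster, SynOp count, optional state traces."""

    raster: np.ndarray  # (n_spikes, 3): tick, core, neuron (global id)
    synop_count: int
    n_ticks: int
    traces: dict[int, np.ndarray] = field(default_factory=dict)  # gid -> (T, k)
    weights: np.ndarray | None = None

    def spike_counts(self, n_neurons: int) -> np.ndarray:
        return np.bincount(self.raster[:, 2], minlength=n_neurons)

    def spikes_of(self, gid: int) -> np.ndarray:
        return self.raster[self.raster[:, 2] == gid, 0]


def count_synops(record: SimRecord) -> int:
    """Total delivered-and-accumulated synaptic events (post blank-out)."""
    return record.synop_count


class Network:
    """A configurable fixed-point spiking network.

    Build with :meth:`add_group` / :meth:`add_input_group` /
    :meth:`connect`, then :meth:`run`.  Neuron ids are global and 0-based;
    input "neurons" have no dynamics and spike only when driven by
    external events.
    """

    def __init__(self, state_width: int = 16, max_delay: int = 64):
        self.state_width = state_width
        self.max_delay = max_delay
        self.groups: list[GroupState] = []
        self.plast_configs: list[PlasticityConfig] = []
        self.n_neurons = 0
        self._k_max = 1
        self._syn: list[tuple] = []  # (pre, post, comp, weight, delay, plast, bl, slot)
        self._n_slots = 0
        self._input_ids: set[int] = set()
        self._finalized = False
        self.seed = 0

    # -- construction -------------------------------------------------------
    def add_group(self, params: NeuronParamGroup, n: int, core: int = 0) -> np.ndarray:
        if self._finalized:
            raise ConfigError("network already finalized")
        g = GroupState(params, self.n_neurons, n, core)
        self.groups.append(g)
        self.n_neurons += n
        self._k_max = max(self._k_max, params.k)
        return np.arange(g.start, g.start + n)

    def add_input_group(self, n: int, core: int = 0) -> np.ndarray:
        """Dynamics-free neurons used as external spike sources."""
        ids = np.arange(self.n_neurons, self.n_neurons + n)
        self.n_neurons += n
        self._input_ids.update(int(i) for i in ids)
        return ids

    def add_plasticity(self, cfg: PlasticityConfig) -> int:
        self.plast_configs.append(cfg)
        return len(self.plast_configs) - 1

    def connect(self, pre, post, comp=0, weight=0, delay=0, plast: int = -1,
                bl_num: int = -1, slot=None):
        """Add synapses (scalars broadcast over array arguments).

        ``bl_num`` sets the blank-out probability to ``bl_num / 256``
        (-1 = deterministic synapse).  ``slot`` shares weight storage with
        previously created synapses (pass the slot ids returned earlier);
        by default each synapse gets its own slot.  Returns the slot ids.
        """
        pre, post, comp, weight, delay, bl = np.broadcast_arrays(
            np.atleast_1d(pre), post, comp, weight, delay, bl_num)
        if slot is None:
            slots = np.arange(self._n_slots, self._n_slots + len(pre))
            self._n_slots += len(pre)
        else:
            slots = np.broadcast_to(np.atleast_1d(slot), pre.shape)
        for i in range(len(pre)):
            self._syn.append((int(pre[i]), int(post[i]), int(comp[i]),
                              int(weight[i]), int(delay[i]), plast,
                              int(bl[i]), int(slots[i])))
        return slots

    # -- finalization --------------------------------------------------------
    def finalize(self) -> None:
        if self._finalized:
            return
        n, k = self.n_neurons, self._k_max
        self.x = np.zeros((n, k), dtype=np.int64)
        self.acc = np.zeros((n, k), dtype=np.int64)
        self.refr = np.zeros(n, dtype=np.int64)
        self.gids = np.arange(n, dtype=np.int64)
        self.bias_extra = np.zeros((n, k), dtype=np.int64)  # per-neuron drive
        self.gain_exp = np.zeros((n, k), dtype=np.int64)
        self.core_of = np.zeros(n, dtype=np.int64)
        for g in self.groups:
            self.gain_exp[g.sl, : g.params.k] = g.params.syn_gain_exp
            self.core_of[g.sl] = g.core
        arr = np.array(self._syn, dtype=np.int64).reshape(-1, 8)
        order = np.argsort(arr[:, 0], kind="stable") if len(arr) else np.array([], int)
        arr = arr[order]
        self.syn_pre = arr[:, 0]
        self.syn_post = arr[:, 1]
        self.syn_comp = arr[:, 2]
        self.syn_w0 = arr[:, 3]
        self.syn_delay = arr[:, 4]
        self.syn_plast = arr[:, 5]
        self.syn_bl = arr[:, 6]
        self.syn_slot = arr[:, 7]
        self.syn_id = order  # creation-order id: the RNG key of a synapse
        bad = (self.syn_post < 0) | (self.syn_post >= n)
        if bad.any():
            raise ConfigError(f"synapse targets nonexistent neuron(s) "
                              f"{np.unique(self.syn_post[bad])}")
        if np.any(self.syn_delay > self.max_delay) or np.any(self.syn_delay < 0):
            raise ConfigError(f"synaptic delays must lie in [0, {self.max_delay}]")
        for g in self.groups:
            onto = np.isin(self.syn_post, self.gids[g.sl])
            if onto.any() and np.any(self.syn_comp[onto] >= g.params.k):
                raise ConfigError("synapse targets unknown state component")
        self.weights = np.zeros(self._n_slots, dtype=np.int64)
        self.weights[self.syn_slot] = self.syn_w0
        self.row_ptr = np.searchsorted(self.syn_pre, np.arange(n + 1))
        # precomputed fanout rows grouped by delay, for fast routing
        self._row_groups: dict[int, tuple] = {}
        for gid in np.unique(self.syn_pre):
            lo, hi = self.row_ptr[gid], self.row_ptr[gid + 1]
            idxs = np.arange(lo, hi)
            delays = self.syn_delay[lo:hi]
            groups = [(int(d), idxs[delays == d]) for d in np.unique(delays)]
            self._row_groups[int(gid)] = (groups,
                                          bool((self.syn_plast[lo:hi] >= 0).any()))
        self.engine = PlasticityEngine(self, self.plast_configs)
        self._finalized = True

    def reset_state(self, weights: bool = False) -> None:
        """Zero neuron states and plasticity timers; optionally re-seed the
        weight pool from the construction-time initial weights."""
        self._due = {}
        self._plast_due = {}
        self.x[:] = 0
        self.acc[:] = 0
        self.refr[:] = 0
        if weights:
            self.weights[self.syn_slot] = self.syn_w0
        self.engine = PlasticityEngine(self, self.plast_configs)

    # -- helpers -------------------------------------------------------------
    def _blankout_for(self, idxs: np.ndarray, emission: int) -> np.ndarray:
        """Replayable per-synapse Bernoulli mask for a spike emitted at
        ``emission`` (keyed at emission + 1, independent of axonal delay)."""
        bl = self.syn_bl[idxs]
        stochastic = bl >= 0
        mask = np.ones(len(idxs), dtype=bool)
        if stochastic.any():
            bits = fxp.uniform_bits(self.seed, self.syn_id[idxs[stochastic]],
                                    emission + 1, fxp.Purpose.BLANKOUT)
            draw = (bits >> np.uint64(64 - BL_DEN_EXP)).astype(np.int64)
            mask[stochastic] = draw < bl[stochastic]
        return mask

    def row(self, gid: int) -> np.ndarray:
        return np.arange(self.row_ptr[gid], self.row_ptr[gid + 1])

    # -- the tick loop --------------------------------------------------------
    def run(self, n_ticks: int, seed: int = 0, events=None, watch=(),
            record_weights: bool = False, reset: bool = True,
            progress: bool = False, plasticity_gate=None,
            start_tick: int = 0) -> SimRecord:
        """Run for ``n_ticks`` ticks; deterministic given (config, seed).

        ``events`` is an (m, 2) or (m, 3) integer array of external input
        events ``(tick, neuron[, delay])`` addressed to input-group
        neurons.  ``watch`` lists global ids whose full state vector is
        traced every tick.  ``plasticity_gate``, if given, is a function
        of the tick; weight updates are suppressed whenever it returns
        False (learn-freeze windows, evaluation phases).  ``start_tick``
        continues a paused simulation (with ``reset=False``) on an
        absolute tick axis, preserving states, timers and delayed events.
        """
        self.finalize()
        if reset:
            self.reset_state()
        self.seed = int(seed)
        if start_tick == 0 or reset:
            self._due = {}
            self._plast_due = {}
        if events is None or len(events) == 0:
            events = np.zeros((0, 3), dtype=np.int64)
        else:
            events = np.asarray(events, dtype=np.int64)
            if events.shape[1] == 2:
                events = np.hstack([events, np.zeros((len(events), 1), np.int64)])
            events = events[np.argsort(events[:, 0], kind="stable")]
            events = events[events[:, 0] >= 0]
        ev_ptr = 0
        watch = list(watch)
        traces = {gid: np.zeros((n_ticks, self._k_max), dtype=np.int64)
                  for gid in watch}
        trace_off = start_tick
        due = self._due            # tick -> [(synapse idx array, emission)]
        plast_due = self._plast_due  # tick -> [(pre, emission)]
        raster: list[tuple[int, int, int]] = []
        synops = 0
        iterator = range(start_tick, start_tick + n_ticks)
        if progress:
            try:
                from tqdm import tqdm
                iterator = tqdm(iterator, desc="run", unit="tick")
            except ImportError:
                pass
        for t in iterator:
            # ---- stage 1: integrate + detect (barrier after all cores) ----
            for g in self.groups:
                g.stage1_integrate(self.x, self.acc, self.refr, self.gids,
                                   t, self.seed, self.bias_extra)
            self.acc[:] = 0
            spike_gids: list[np.ndarray] = []
            for g in self.groups:
                loc = g.apply_thresholds(self.x, self.refr)
                if len(loc):
                    spike_gids.append(loc + g.start)
            spikes = (np.concatenate(spike_gids) if spike_gids
                      else np.zeros(0, dtype=np.int64))
            for gid in spikes:
                raster.append((t, int(self.core_of[gid]), int(gid)))
            # ---- routing (barrier): schedule deliveries at t + 1 + delay ----
            self._route(spikes, t, t, due, plast_due)
            # external events stamped t: emitted at t - 1 by convention
            while ev_ptr < len(events) and events[ev_ptr, 0] == t:
                ev = events[ev_ptr]
                self._route(np.array([ev[1]]), t - 1, t - 1 + ev[2],
                            due, plast_due)
                ev_ptr += 1
            # ---- stage 2: accumulate + learn ----
            self.engine.register_post_spikes(spikes, t)
            batch = due.pop(t, None)
            if batch:
                idxs = np.concatenate([b for b, _ in batch])
                emis = np.concatenate(
                    [np.full(len(b), e, dtype=np.int64) for b, e in batch])
                mask = np.ones(len(idxs), dtype=bool)
                for e in np.unique(emis):
                    seli = emis == e
                    mask[seli] = self._blankout_for(idxs[seli], int(e))
                idxs = idxs[mask]
                if len(idxs):
                    w = self.weights[self.syn_slot[idxs]]
                    contrib = shift_mult_varexp(
                        self.gain_exp[self.syn_post[idxs], self.syn_comp[idxs]],
                        w, ACC_WIDTH)
                    np.add.at(self.acc, (self.syn_post[idxs], self.syn_comp[idxs]),
                              contrib)
                    lo, hi = fxp.sat_bounds(ACC_WIDTH)
                    np.clip(self.acc, lo, hi, out=self.acc)
                    synops += len(idxs)
            if plasticity_gate is None or plasticity_gate(t):
                for pre, emission in plast_due.pop(t, ()):  # pre-sensitive
                    self.engine.on_pre_event(pre, emission, t)
                self.engine.on_expiries(t)
            else:
                plast_due.pop(t, None)
                self.engine.expiry.pop(t, None)
            for gid in watch:
                traces[gid][t - trace_off] = self.x[gid]
        rast = (np.array(raster, dtype=np.int64) if raster
                else np.zeros((0, 3), dtype=np.int64))
        return SimRecord(raster=rast, synop_count=synops,
                         n_ticks=start_tick + n_ticks,
                         traces=traces,
                         weights=self.weights.copy() if record_weights else None)

    def _route(self, srcs: np.ndarray, emission: int, base_tick: int,
               due: dict, plast_due: dict) -> None:
        """Schedule fanout deliveries of spikes emitted at ``emission``;
        delivery tick = base_tick + 1 + synaptic delay."""
        for gid in srcs:
            entry = self._row_groups.get(int(gid))
            if entry is None:
                continue
            groups, plastic = entry
            for d, idxs in groups:
                due.setdefault(base_tick + 1 + d, []).append((idxs, emission))
            if plastic:
                plast_due.setdefault(base_tick + 1, []).append(
                    (int(gid), emission))
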