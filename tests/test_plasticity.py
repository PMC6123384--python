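"""Event-driven STDP engine: kernel, nearest-neighbor pairing, modulation,
clipping, and equivalence with a brute-force offline oracle."""

import numpy as np
import pytest

from spikefx import (Network, NeuronParamGroup, PlasticityConfig,
                     STDPKernelConfig)
from spikefx.plasticity import nearest_neighbor_stdp_oracle


class TestKernel:
    def test_peak_and_window(self):
        k = STDPKernelConfig(t_ca=32, t_ac=16, ca_exp=3, ac_exp=2,
                             mode="exp", half_decay=8)
        assert k.eval(0) == (1, 3)          # causal peak
        assert k.eval(8) == (1, 2)          # one half-decay step down
        assert k.eval(33) is None           # outside the causal window
        assert k.eval(-1) == (-1, 2)        # acausal side
        assert k.eval(-17) is None

    def test_linear_staircase(self):
        k = STDPKernelConfig(t_ca=12, t_ac=12, ca_exp=4, ac_exp=4,
                             mode="linear",
                             breakpoints_ca=((4, 2), (8, 0)))
        ca, _ = k.tables()
        assert list(ca) == [4] * 4 + [2] * 4 + [0] * 5

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            STDPKernelConfig(t_ca=0)


def pair_network(kernel, refractory=40, mod=16, r=0, w0=0,
                 w_min=-30000, w_max=30000):
    """An input 'pre' neuron with one plastic synapse onto a post neuron
    whose modulator component is held constant; a second input forces the
    post neuron to spike on command."""
    net = Network()
    pre = net.add_input_group(1)[0]
    drv = net.add_input_group(1)[0]
    g = NeuronParamGroup(
        k=2, A_sign=np.array([[-1, 0], [0, -1]]), A_exp=np.zeros((2, 2)),
        b=np.array([0, mod]), theta=np.array([100, 32767]),
        reset_enable=np.array([True, False]), Xr=np.zeros(2),
        refractory_period=refractory, modulator_index=1)
    post = net.add_group(g, 1)[0]
    cfg = net.add_plasticity(PlasticityConfig(
        kernel=kernel, w_min=w_min, w_max=w_max, r=r, mod_idx=1))
    net.connect(pre, post, comp=0, weight=w0, plast=cfg)
    net.connect(drv, post, comp=0, weight=200)
    return net, pre, drv, post


def run_pair(pre_stamps, drv_stamps, kernel, **kw):
    """Returns (final weight, post spike ticks, pre emission ticks)."""
    net, pre, drv, post = pair_network(kernel, **kw)
    ev = sorted([(int(t), pre) for t in pre_stamps]
                + [(int(t), drv) for t in drv_stamps])
    horizon = (max(t for t, _ in ev) + kernel.t_ca + 5) if ev else 10
    rec = net.run(horizon, seed=3, events=np.array(ev, dtype=np.int64),
                  record_weights=True)
    return int(rec.weights[0]), rec.spikes_of(post), \
        np.asarray(pre_stamps, dtype=np.int64) - 1


KER = STDPKernelConfig(t_ca=32, t_ac=32, ca_exp=2, ac_exp=1,
                       mode="exp", half_decay=12)


class TestEventPipelines:
    def test_acausal_single_pair(self):
        """Post fires 5 ticks before pre: one acausal (depressing) delta."""
        w, post_spikes, pre_emis = run_pair([101], [95], KER)
        assert post_spikes[0] == 96  # driver event at 95 integrates at 96
        assert w == nearest_neighbor_stdp_oracle(pre_emis, post_spikes,
                                                 KER, 16)
        assert w < 0

    def test_causal_single_pair_committed_on_expiry(self):
        """Post fires 3 ticks after pre; the causal update is committed
        when the pre timer expires."""
        w, post_spikes, pre_emis = run_pair([101], [103], KER)
        lag = post_spikes[0] - pre_emis[0]
        sign, e = KER.eval(int(lag))
        assert w == sign * (16 << e)
        assert w > 0

    def test_no_post_spike_no_delta(self):
        w, _, _ = run_pair([101], [], KER)
        assert w == 0

    def test_outside_window_no_delta(self):
        w, _, _ = run_pair([150], [100], KER)  # lag 49 > t_ac
        assert w == 0

    def test_two_posts_after_pre_nearest_wins(self):
        """Two post spikes inside one causal window: only the earlier
        (nearest) one pairs with the pre spike."""
        k = STDPKernelConfig(t_ca=32, t_ac=32, ca_exp=2, ac_exp=1,
                             mode="exp", half_decay=6)
        w, post_spikes, pre_emis = run_pair([101], [104, 119], k,
                                            refractory=10)
        lag = int(post_spikes[0] - pre_emis[0])
        sign, e = k.eval(lag)
        assert w == sign * (16 << e)

    def test_plasticity_disabled_conserves_weights(self):
        """With no plasticity config, weights never change."""
        net = Network()
        pre = net.add_input_group(1)[0]
        g = NeuronParamGroup.diag_leak(1, [0], signs=[0],
                                       theta=np.array([50]),
                                       reset_enable=np.array([True]))
        post = net.add_group(g, 1)[0]
        net.connect(pre, post, weight=60)
        ev = np.column_stack([np.arange(0, 50, 3), np.zeros(17, np.int64)])
        rec = net.run(60, seed=1, events=ev, record_weights=True)
        assert len(rec.raster) > 0
        assert rec.weights[0] == 60


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_poisson_pairs_match_oracle_exactly(self, seed):
        """Random Poisson pre/post trains with refractory >= window: the
        event-driven total weight change equals brute-force
        nearest-neighbor STDP, integer for integer."""
        rng = np.random.default_rng(seed)
        refractory = 40
        pre_stamps, last = [], -100
        for t in np.nonzero(rng.random(4000) < 0.02)[0] + 1:
            if t - last > refractory:
                pre_stamps.append(int(t))
                last = t
        drv_stamps = (np.nonzero(rng.random(4000) < 0.02)[0] + 1).tolist()
        w, post_spikes, pre_emis = run_pair(pre_stamps, drv_stamps, KER,
                                            refractory=refractory)
        assert w == nearest_neighbor_stdp_oracle(pre_emis, post_spikes,
                                                 KER, 16)


class TestModulationAndClipping:
    def test_zero_modulator_no_update(self):
        w, _, _ = run_pair([101], [103], KER, mod=0)
        assert w == 0

    def test_update_linear_in_modulator(self):
        w1, _, _ = run_pair([101], [103], KER, mod=16)
        w2, _, _ = run_pair([101], [103], KER, mod=32)
        assert w2 == 2 * w1

    def test_clip_at_bounds(self):
        w, _, _ = run_pair([101], [103], KER, w0=127, w_min=-128, w_max=127)
        assert w == 127
        w, _, _ = run_pair([101], [95], KER, w0=-128, w_min=-128, w_max=127)
        assert w == -128

    def test_weights_never_leave_bounds_under_dense_traffic(self):
        rng = np.random.default_rng(5)
        pre_stamps, last = [], -100
        for t in np.nonzero(rng.random(3000) < 0.05)[0] + 1:
            if t - last > 40:
                pre_stamps.append(int(t))
                last = t
        drv_stamps = (np.nonzero(rng.random(3000) < 0.05)[0] + 1).tolist()
        net, pre, drv, post = pair_network(KER, w_min=-20, w_max=20, w0=0)
        ev = sorted([(t, pre) for t in pre_stamps]
                    + [(t, drv) for t in drv_stamps])
        # weight is clipped within [-20, 20] throughout, not just at the end
        tick = 0
        for seg in range(6):
            net.run(500, seed=2, reset=False, start_tick=tick,
                    events=np.array([e for e in ev
                                     if tick <= e[0] < tick + 500]))
            tick += 500
            assert -20 <= net.weights[0] <= 20

    def test_randomized_rounding_of_unit_delta(self):
        """delta=16 at r=6 commits +1 with probability 1/4 (never more)."""
        outcomes = []
        for s in range(40):
            net, pre, drv, post = pair_network(
                STDPKernelConfig(t_ca=8, t_ac=8, ca_exp=0, ac_exp=0),
                r=6, mod=16)
            ev = np.array([[101, pre], [103, drv]], dtype=np.int64)
            rec = net.run(120, seed=s, events=ev, record_weights=True)
            outcomes.append(int(rec.weights[0]))
        assert set(outcomes) <= {0, 1}
        assert 0 < np.mean(outcomes) < 0.8


class TestForwardOnlyAccess:
    def test_only_firing_pre_rows_touched(self):
        """The engine reads only synapse-table rows of neurons that fired
        (or whose timer expired): no reverse lookups."""
        net, pre, drv, post = pair_network(KER)
        ev = np.array([[101, pre], [95, drv], [103, drv]], dtype=np.int64)
        net.run(200, seed=1)
        net.reset_state()
        rec = net.run(200, seed=1, events=ev)
        assert set(net.engine.row_accesses) <= {pre}

    def test_timer_memory_is_per_neuron(self):
        """Timer state arrays scale with neuron count, not synapse count."""
        net = Network()
        pre = net.add_input_group(10)
        g = NeuronParamGroup.diag_leak(1, [-2], theta=np.array([100]),
                                       reset_enable=np.array([True]))
        post = net.add_group(g, 10)
        cfg = net.add_plasticity(PlasticityConfig(kernel=KER))
        net.connect(np.repeat(pre, 10), np.tile(post, 10), weight=1,
                    plast=cfg)
        net.finalize()
        eng = net.engine
        assert eng.last_pre.shape == (net.n_neurons,)
        assert eng.hist.shape[0] == net.n_neurons
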