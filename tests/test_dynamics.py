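"""Neuron-group integration, threshold/reset and refractory semantics."""

import numpy as np
import pytest

from spikefx import Network, NeuronParamGroup, ConfigError
from spikefx.dynamics import NOISE_OFF


def single_neuron(A_sign, A_exp, b, theta=1 << 14, reset=True, Xr=0,
                  refractory=0, k=1, **kw):
    g = NeuronParamGroup(
        k=k, A_sign=np.asarray(A_sign), A_exp=np.asarray(A_exp),
        b=np.atleast_1d(b), theta=np.r_[theta, [32767] * (k - 1)],
        reset_enable=np.r_[reset, [False] * (k - 1)].astype(bool),
        Xr=np.r_[Xr, [0] * (k - 1)], refractory_period=refractory, **kw)
    net = Network()
    net.add_group(g, 1)
    net.finalize()
    return net


class TestStage1:
    def test_pure_leak_quarter(self):
        net = single_neuron([[-1]], [[-2]], [0])
        net.finalize()
        net.x[0, 0] = 100
        rec = net.run(1, seed=0, reset=False, watch=[0])
        assert rec.traces[0][0, 0] == 75  # 100 - 100/4

    def test_linear_integrator(self):
        """Zero transition matrix + constant bias integrates linearly."""
        net = single_neuron([[0]], [[0]], [5])
        rec = net.run(4, seed=0, watch=[0])
        assert list(rec.traces[0][:, 0]) == [5, 10, 15, 20]

    def test_minimum_decay(self):
        net = single_neuron([[-1]], [[-4]], [0])
        net.finalize()
        net.x[0, 0] = 3
        rec = net.run(1, seed=0, reset=False, watch=[0])
        assert rec.traces[0][0, 0] == 2

    def test_saturation_never_wraps(self):
        net = single_neuron([[0]], [[0]], [30000], theta=32767, reset=False)
        rec = net.run(10, seed=0, watch=[0])
        assert rec.traces[0][-1, 0] == 32767

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            NeuronParamGroup(k=2, A_sign=np.zeros((1, 1)),
                             A_exp=np.zeros((2, 2)), b=np.zeros(2),
                             theta=np.zeros(2),
                             reset_enable=np.zeros(2, bool), Xr=np.zeros(2))


class TestThresholds:
    def test_spike_at_exact_threshold(self):
        """Comparison is >=: reaching theta exactly emits a spike."""
        net = single_neuron([[0]], [[0]], [10], theta=20)
        rec = net.run(3, seed=0)
        assert list(rec.spikes_of(0)) == [1]  # 10, 20 -> spike

    def test_below_threshold_no_spike(self):
        net = single_neuron([[0]], [[0]], [10], theta=21)
        rec = net.run(2, seed=0)
        assert len(rec.raster) == 0

    def test_no_reset_mode_keeps_state_and_spikes(self):
        """Reset disabled (neural-field mode): state rides above threshold
        and the neuron fires every tick."""
        net = single_neuron([[0]], [[0]], [10], theta=20, reset=False)
        rec = net.run(5, seed=0, watch=[0])
        assert list(rec.spikes_of(0)) == [1, 2, 3, 4]
        assert rec.traces[0][-1, 0] == 50  # never reset

    def test_auxiliary_component_conditional_reset(self):
        """A non-spiking component resets independently of spiking."""
        g = NeuronParamGroup(
            k=2, A_sign=np.zeros((2, 2)), A_exp=np.zeros((2, 2)),
            b=np.array([0, 7]), theta=np.array([32767, 20]),
            reset_enable=np.array([False, True]), Xr=np.array([0, 3]))
        net = Network()
        net.add_group(g, 1)
        rec = net.run(6, seed=0, watch=[0])
        assert len(rec.raster) == 0  # component 1 resets produce no spikes
        x1 = list(rec.traces[0][:, 1])
        assert x1 == [7, 14, 3, 10, 17, 3]  # 21 >= 20 -> reset to 3


class TestRefractory:
    def test_never_spikes_during_refractory(self):
        """Strong constant drive cannot elicit spikes inside the
        refractory window, for any input magnitude."""
        net = single_neuron([[0]], [[0]], [30000], theta=100, refractory=7)
        rec = net.run(40, seed=0)
        isis = np.diff(rec.spikes_of(0))
        assert (isis >= 8).all()

    def test_clamp_holds_component0_only(self):
        g = NeuronParamGroup(
            k=2, A_sign=np.zeros((2, 2)), A_exp=np.zeros((2, 2)),
            b=np.array([50, 3]), theta=np.array([100, 32767]),
            reset_enable=np.array([True, False]), Xr=np.array([0, 0]),
            refractory_period=3)
        net = Network()
        net.add_group(g, 1)
        rec = net.run(8, seed=0, watch=[0])
        tr = rec.traces[0]
        spike = rec.spikes_of(0)[0]
        assert tr[spike + 1, 0] == 0        # clamped at reset
        # component 1 keeps integrating through the refractory period
        assert all(np.diff(tr[:, 1]) == 3)


class TestAccumulation:
    def test_synaptic_gain_shift(self):
        net = Network()
        src = net.add_input_group(1)[0]
        g = NeuronParamGroup.diag_leak(1, [0], signs=[0],
                                       syn_gain_exp=np.array([2]))
        tgt = net.add_group(g, 1)[0]
        net.connect(src, tgt, weight=10)
        rec = net.run(4, seed=0, events=np.array([[1, src]]), watch=[tgt])
        # delivered in stage 2 of tick 1 -> visible in stage 1 of tick 2
        assert rec.traces[tgt][2, 0] == 40

    def test_blankout_drop_and_pass(self):
        """p=1 passes every delivery, p=0 drops every delivery."""
        for bl, expect in ((256, 50), (0, 0)):
            net = Network()
            src = net.add_input_group(1)[0]
            g = NeuronParamGroup.diag_leak(1, [0], signs=[0])
            tgt = net.add_group(g, 1)[0]
            net.connect(src, tgt, weight=50, bl_num=bl)
            rec = net.run(3, seed=0, events=np.array([[0, src]]),
                          watch=[tgt])
            assert rec.traces[tgt][-1, 0] == expect

    def test_mean_under_blankout(self):
        """Accumulated drive under p=1/2 blank-out converges to half the
        deterministic value (3-sigma band)."""
        net = Network()
        srcs = net.add_input_group(1)
        g = NeuronParamGroup.diag_leak(1, [0], signs=[0])
        tgts = net.add_group(g, 400)
        net.connect(np.repeat(srcs, 400), tgts, weight=8, bl_num=128)
        n_ev = 50
        ev = np.column_stack([np.arange(n_ev), np.full(n_ev, srcs[0])])
        rec = net.run(n_ev + 2, seed=3, events=ev, watch=list(tgts[:50]))
        total = sum(rec.traces[t][-1, 0] for t in tgts[:50])
        n_draws = 50 * n_ev
        expect = 0.5 * 8 * n_draws
        sigma = 8 * np.sqrt(n_draws * 0.25)
        assert abs(total - expect) < 3 * sigma

    def test_unknown_component_rejected(self):
        net = Network()
        src = net.add_input_group(1)[0]
        g = NeuronParamGroup.diag_leak(1, [0])
        tgt = net.add_group(g, 1)[0]
        net.connect(src, tgt, comp=3, weight=1)
        with pytest.raises(ConfigError):
            net.finalize()


class TestPSPShape:
    def test_difference_of_exponentials(self):
        """Membrane driven by a synaptic-current compartment: one input
        spike produces a rise-then-decay PSP on the membrane."""
        net = Network()
        src = net.add_input_group(1)[0]
        g = NeuronParamGroup(
            k=2,
            A_sign=np.array([[-1, 1], [0, -1]]),
            A_exp=np.array([[-4, -2], [0, -2]]),
            b=np.zeros(2), theta=np.array([32767, 32767]),
            reset_enable=np.zeros(2, bool), Xr=np.zeros(2))
        tgt = net.add_group(g, 1)[0]
        net.connect(src, tgt, comp=1, weight=100)
        rec = net.run(60, seed=0, events=np.array([[0, src]]), watch=[tgt])
        v = rec.traces[tgt][:, 0].astype(float)
        peak = int(v.argmax())
        assert v[peak] > 0
        assert 0 < peak < 40
        assert (np.diff(v[:peak + 1]) >= 0).all()
        assert v[-1] < v[peak] / 2  # decays back toward rest


class TestLeakToRestNetwork:
    @pytest.mark.parametrize("e", range(1, 7))
    def test_diagonal_network_decays_to_zero(self, e):
        """Any diagonal-leak group with inputs off decays monotonically in
        |x| to exactly 0 from random initial states."""
        rng = np.random.default_rng(e)
        net = Network()
        g = NeuronParamGroup.diag_leak(2, [-e, -e])
        ids = net.add_group(g, 100)
        net.finalize()
        net.x[ids, :2] = rng.integers(-32768, 32768, size=(100, 2))
        prev = np.abs(net.x[ids, :2]).copy()
        for t in range(200000):
            net.run(1, seed=0, reset=False, start_tick=t)
            cur = np.abs(net.x[ids, :2])
            assert np.all((cur < prev) | (prev == 0))
            prev = cur
            if not cur.any():
                break
        assert not net.x[ids, :2].any()
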