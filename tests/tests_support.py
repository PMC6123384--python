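"""Shared helpers for the test-suite (not a test module)."""

import numpy as np

from spikefx import Network, NeuronParamGroup


def random_recurrent_network(n=200, cores=1, seed=7):
    """A noisy random recurrent network with blank-out synapses and axonal
    delays, its neurons split evenly over ``cores`` cores.  The wiring is
    a pure function of ``seed`` and independent of the partition."""
    rng = np.random.default_rng(seed)
    net = Network()
    per = n // cores
    ids = []
    for c in range(cores):
        g = NeuronParamGroup.diag_leak(
            2, [-3, -4], b=np.array([30, 0]), theta=np.array([290, 32767]),
            reset_enable=np.array([True, False]), Xr=np.array([0, 0]),
            noise_exp=np.array([8, -128]), refractory_period=3)
        ids.append(net.add_group(g, per, core=c))
    ids = np.concatenate(ids)
    m = 6 * n
    pre = rng.integers(0, n, m)
    post = rng.integers(0, n, m)
    w = rng.integers(-40, 60, m)
    delay = rng.integers(0, 4, m)
    net.connect(ids[pre], ids[post], comp=0, weight=w, delay=delay,
                bl_num=128)
    return net
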