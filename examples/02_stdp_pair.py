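"""Nearest-neighbor STDP on a single synapse, against the offline oracle.

A pre-synaptic input is paired with a driven post-synaptic neuron whose
modulator state is held at 16.  The event-driven engine computes causal
(post-after-pre) and acausal (post-before-pre) updates using only
forward synapse-table lookups; the same total is recomputed offline by a
brute-force nearest-neighbor pairing over the complete spike record.
The two integers printed must be identical.
"""

import numpy as np

from spikefx import (Network, NeuronParamGroup, PlasticityConfig,
                     STDPKernelConfig)
from spikefx.plasticity import nearest_neighbor_stdp_oracle

kernel = STDPKernelConfig(t_ca=32, t_ac=32, ca_exp=2, ac_exp=1,
                          mode="exp", half_decay=12)

net = Network()
pre = net.add_input_group(1)[0]
driver = net.add_input_group(1)[0]
g = NeuronParamGroup(
    k=2, A_sign=np.array([[-1, 0], [0, -1]]), A_exp=np.zeros((2, 2)),
    b=np.array([0, 16]), theta=np.array([100, 32767]),
    reset_enable=np.array([True, False]), Xr=np.zeros(2),
    refractory_period=40, modulator_index=1)
post = net.add_group(g, 1)[0]
cfg = net.add_plasticity(PlasticityConfig(kernel=kernel, w_min=-30000,
                                          w_max=30000, r=0, mod_idx=1))
net.connect(pre, post, comp=0, weight=0, plast=cfg)
net.connect(driver, post, comp=0, weight=200)

rng = np.random.default_rng(4)
pre_stamps = np.sort(rng.choice(np.arange(50, 3000, 45), 30, replace=False))
drv_stamps = np.nonzero(rng.random(3000) < 0.02)[0]
events = np.array(sorted([(int(t), pre) for t in pre_stamps]
                         + [(int(t), driver) for t in drv_stamps]),
                  dtype=np.int64)
record = net.run(3100, seed=1, events=events, record_weights=True)

post_spikes = record.spikes_of(post)
oracle = nearest_neighbor_stdp_oracle(pre_stamps - 1, post_spikes, kernel, 16)
print(f"pre spikes: {len(pre_stamps)}, post spikes: {len(post_spikes)}")
print("event-driven engine total weight change:", int(record.weights[0]))
print("brute-force nearest-neighbor oracle:    ", oracle)
# Both totals are the same integer: the forward-table engine is an exact
# implementation of nearest-neighbor STDP in this regime.
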