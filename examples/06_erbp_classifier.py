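"""Supervised classification with event-driven random back-propagation.

A 16-10-2 spiking network learns a two-class Poisson-pattern task: per
class a fixed random half of the 16 inputs fires at 50 Hz (the rest at
4 Hz).  Spiking error neurons compare prediction and label rates; their
spikes modulate membrane-gated plasticity through a fixed random
zero-sum feedback projection (no weight transport).  The script trains
for 200 presentations and prints the held-out accuracy at three
checkpoints: chance (0.5) before training, rising toward 1.0.
"""

from spikefx.models import erbp

accs, checkpoints, net = erbp.train_erbp(n_present=200, seed=0,
                                         eval_every=100)
for n, acc in zip(checkpoints, accs):
    print(f"after {n:3d} presentations: accuracy {acc:.2f}")
# the first row is the untrained network (chance); accuracy climbs as the
# error-modulated updates align hidden and output weights with the task.
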