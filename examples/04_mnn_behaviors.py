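"""The six generalized integrate-and-fire firing behaviors.

Each preset configures one multi-compartment neuron (difference-to-
threshold coordinate, optional adaptation / after-spike currents) and
runs it for one second of simulated time.  The script prints the spike
count and the first few inter-spike intervals per preset, then the f-I
onset rates that separate class I (continuous, arbitrarily slow onset)
from class II (discontinuous jump to fast firing) excitability.
"""

import numpy as np

from spikefx.models import mnn

for preset in mnn.PRESETS:
    rec = mnn.run_preset(preset, ticks=1000, seed=0)
    s = rec.spikes_of(0)
    isis = np.diff(s)
    print(f"{preset:12s} spikes {len(s):3d}  first ISIs {[int(i) for i in isis[:6]]}")

for preset in ("classI", "classII"):
    rates = mnn.fi_curve(preset, mnn._FI_BIASES, seed=0)
    onset = rates[rates > 0]
    print(f"{preset}: lowest nonzero firing rate {onset.min():.1f} Hz")
# tonic fires with a constant interval; phasic only at stimulus onset;
# mixed starts fast and settles slower; tonic-burst alternates short
# intra-burst and long inter-burst intervals.  class I can fire at a few
# Hz near rheobase, class II jumps straight to tens of Hz.
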