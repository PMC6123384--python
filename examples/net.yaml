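# A minimal run configuration: two Poisson-driven leaky cells with an
# STDP synapse from the input channels.  Run with:
#   spikefx validate --config examples/net.yaml
#   spikefx run --config examples/net.yaml --out out/
n_ticks: 500
seed: 7
input: {n_channels: 2}
groups:
  - name: cells
    n: 2
    k: 2
    A: [[[-1, -3], 0], [0, [-1, -4]]]
    b: [40, 16]
    theta: [300, null]
    reset_enable: [true, false]
    Xr: [0, 0]
    refractory: 5
    modulator_index: 1
plasticity:
  - name: stdp
    kernel: {t_ca: 16, t_ac: 16, ca_exp: 1, ac_exp: 0}
    r: 0
    mod_idx: 1
synapses:
  - {pre: "input", post: "cells", weight: 90, plast: stdp, bl_num: 128}
watch: ["cells:0"]
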