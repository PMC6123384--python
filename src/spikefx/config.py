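"""Run configuration: a nested key-value (YAML) document -> Network.

A run configuration describes neuron groups, plasticity rules, the
synapse table, external inputs and run settings.  Parsing validates
everything it can and reports *all* failures at once, each with the
location of the offending key.

Schema sketch (all sections optional except ``groups``/``synapses`` as
needed)::

    state_width: 16
    max_delay: 64
    n_ticks: 1000
    seed: 7
    input: {n_channels: 4, core: 0}     # input neurons get the first ids
    groups:
      - name: main
        n: 10
        core: 0
        k: 2
        A: [[[-1, -4], 0], [0, [-1, 0]]]   # 0 or [sign, exponent]
        b: [5, 0]
        theta: [100, null]                  # null -> never crosses
        reset_enable: [true, false]
        Xr: [0, 0]
        noise_exp: [null, 4]                # null -> noise off
        refractory: 3
        modulator_index: 1
        syn_gain_exp: [0, 0]
    plasticity:
      - name: stdp
        kernel: {t_ca: 32, t_ac: 32, ca_exp: 2, ac_exp: 1,
                 mode: exp, half_decay: 16}
        w_min: -128
        w_max: 127
        r: 6
        mod_idx: 1
    synapses:
      - {pre: 0, post: "main", comp: 0, weight: 10, plast: stdp, bl_num: 128}
    watch: ["main:0"]

Neuron references are global integer ids, a group name (all of the
group), or ``"name:i"`` (the i-th neuron of a group).  Weights must fit
the 8-bit synaptic range; shift exponents are bounded by the fixed-point
convention (|exponent| <= 15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dynamics import ConfigError, NeuronParamGroup, NOISE_OFF
from .fxp import MAX_EXP, sat_bounds
from .network import Network
from .plasticity import PlasticityConfig, STDPKernelConfig

__all__ = ["RunConfig", "parse_config", "ValidationFailure"]

WEIGHT_BOUNDS = (-128, 127)


@dataclass(frozen=True)
class ValidationFailure:
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


@dataclass
class RunConfig:
    """A validated run description; :meth:`build` instantiates the network."""

    doc: dict
    group_ids: dict[str, np.ndarray] = field(default_factory=dict)
    plast_ids: dict[str, int] = field(default_factory=dict)
    n_ticks: int = 0
    seed: int = 0
    watch: list[int] = field(default_factory=list)

    def build(self) -> Network:
        net = Network(state_width=self.doc.get("state_width", 16),
                      max_delay=self.doc.get("max_delay", 64))
        inp = self.doc.get("input")
        if inp:
            self.group_ids["input"] = net.add_input_group(
                inp["n_channels"], core=inp.get("core", 0))
        for gdoc in self.doc.get("groups", []):
            params = _group_params(gdoc)
            self.group_ids[gdoc.get("name", f"group{len(self.group_ids)}")] = \
                net.add_group(params, gdoc.get("n", 1), core=gdoc.get("core", 0))
        for pdoc in self.doc.get("plasticity", []):
            cfg = _plast_config(pdoc)
            self.plast_ids[pdoc.get("name", f"plast{len(self.plast_ids)}")] = \
                net.add_plasticity(cfg)
        for sdoc in self.doc.get("synapses", []):
            pre = self._resolve(sdoc["pre"])
            post = self._resolve(sdoc["post"])
            if len(pre) != len(post):
                if len(pre) == 1:
                    pre = np.repeat(pre, len(post))
                elif len(post) == 1:
                    post = np.repeat(post, len(pre))
                else:  # dense product
                    pre, post = (np.repeat(pre, len(post)),
                                 np.tile(post, len(pre)))
            plast = sdoc.get("plast", -1)
            if isinstance(plast, str):
                plast = self.plast_ids[plast]
            net.connect(pre, post, comp=sdoc.get("comp", 0),
                        weight=sdoc.get("weight", 0),
                        delay=sdoc.get("delay", 0), plast=plast,
                        bl_num=sdoc.get("bl_num", -1))
        self.n_ticks = self.doc.get("n_ticks", 0)
        self.seed = self.doc.get("seed", 0)
        self.watch = [int(self._resolve(w)[0]) for w in self.doc.get("watch", [])]
        net.finalize()
        return net

    def _resolve(self, ref) -> np.ndarray:
        if isinstance(ref, (int, np.integer)):
            return np.array([ref], dtype=np.int64)
        if isinstance(ref, (list, tuple)):
            return np.concatenate([self._resolve(r) for r in ref])
        if isinstance(ref, str):
            if ":" in ref:
                name, idx = ref.rsplit(":", 1)
                return self.group_ids[name][[int(idx)]]
            return self.group_ids[ref]
        raise ConfigError(f"cannot resolve neuron reference {ref!r}")


def _coeff(entry, loc, failures):
    if entry in (0, None):
        return 0, 0
    try:
        sign, exp = entry
    except (TypeError, ValueError):
        failures.append(ValidationFailure(loc, f"matrix entry must be 0 or "
                                               f"[sign, exponent], got {entry!r}"))
        return 0, 0
    if isinstance(sign, str):
        sign = {"+": 1, "-": -1}.get(sign, sign)
    if sign not in (-1, 0, 1):
        failures.append(ValidationFailure(loc, f"sign must be -1/0/+1, got {sign!r}"))
        sign = 0
    if abs(int(exp)) > MAX_EXP:
        failures.append(ValidationFailure(loc, f"|exponent| must be <= {MAX_EXP}, "
                                               f"got {exp}"))
        exp = 0
    return int(sign), int(exp)


def _group_params(gdoc, failures=None) -> NeuronParamGroup:
    failures = [] if failures is None else failures
    k = gdoc.get("k", 1)
    A = gdoc.get("A", [[0] * k for _ in range(k)])
    A_sign = np.zeros((k, k), dtype=np.int8)
    A_exp = np.zeros((k, k), dtype=np.int8)
    for i in range(k):
        for j in range(k):
            s, e = _coeff(A[i][j], f"groups[{gdoc.get('name')}].A[{i}][{j}]",
                          failures)
            A_sign[i, j], A_exp[i, j] = s, e
    width = gdoc.get("width", 16)
    hi = sat_bounds(width)[1]
    theta = [hi if v is None else v for v in gdoc.get("theta", [hi] * k)]
    noise = [NOISE_OFF if v is None else v for v in gdoc.get("noise_exp",
                                                             [None] * k)]
    return NeuronParamGroup(
        k=k, A_sign=A_sign, A_exp=A_exp,
        b=np.asarray(gdoc.get("b", [0] * k)),
        theta=np.asarray(theta),
        reset_enable=np.asarray(gdoc.get("reset_enable", [False] * k)),
        Xr=np.asarray(gdoc.get("Xr", [0] * k)),
        noise_exp=np.asarray(noise),
        refractory_period=gdoc.get("refractory", 0),
        modulator_index=gdoc.get("modulator_index", 0),
        syn_gain_exp=np.asarray(gdoc.get("syn_gain_exp", [0] * k)),
        width=width, name=gdoc.get("name", ""))


def _plast_config(pdoc) -> PlasticityConfig:
    kdoc = pdoc.get("kernel", {})
    kernel = STDPKernelConfig(
        t_ca=kdoc.get("t_ca", 32), t_ac=kdoc.get("t_ac", 32),
        ca_exp=kdoc.get("ca_exp", 0), ac_exp=kdoc.get("ac_exp", 0),
        ca_sign=kdoc.get("ca_sign", 1), ac_sign=kdoc.get("ac_sign", -1),
        mode=kdoc.get("mode", "exp"), half_decay=kdoc.get("half_decay", 16),
        breakpoints_ca=tuple(map(tuple, kdoc.get("breakpoints_ca", ()))),
        breakpoints_ac=tuple(map(tuple, kdoc.get("breakpoints_ac", ()))))
    gate = pdoc.get("gate")
    return PlasticityConfig(
        kernel=kernel, w_min=pdoc.get("w_min", -128),
        w_max=pdoc.get("w_max", 127), r=pdoc.get("r", 0),
        mod_idx=pdoc.get("mod_idx", 0),
        modulation_mode=pdoc.get("modulation_mode", "mod-by-kernel"),
        gate_comp=None if gate is None else gate["comp"],
        gate_min=0 if gate is None else gate.get("min", 0),
        gate_max=0 if gate is None else gate.get("max", 0),
        update_on_dropped=pdoc.get("update_on_dropped", True),
        state_driven=pdoc.get("state_driven", False))


def parse_config(text: str):
    """Parse + validate.  Returns (RunConfig, failures); the RunConfig is
    usable only when ``failures`` is empty."""
    failures: list[ValidationFailure] = []
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        return None, [ValidationFailure("document", f"YAML error: {exc}")]
    if not isinstance(doc, dict):
        return None, [ValidationFailure("document", "top level must be a mapping")]
    known = {"state_width", "max_delay", "n_ticks", "seed", "input", "groups",
             "plasticity", "synapses", "watch"}
    for key in doc:
        if key not in known:
            failures.append(ValidationFailure(key, "unknown key"))
    names = set()
    for i, gdoc in enumerate(doc.get("groups", [])):
        loc = f"groups[{i}]"
        try:
            _group_params(gdoc, failures)
        except (ConfigError, KeyError, TypeError, IndexError) as exc:
            failures.append(ValidationFailure(loc, str(exc)))
        names.add(gdoc.get("name", f"group{i}"))
    if doc.get("input"):
        names.add("input")
    pnames = set()
    for i, pdoc in enumerate(doc.get("plasticity", [])):
        loc = f"plasticity[{i}]"
        try:
            cfg = _plast_config(pdoc)
            if not (WEIGHT_BOUNDS[0] <= cfg.w_min < cfg.w_max <= WEIGHT_BOUNDS[1]):
                failures.append(ValidationFailure(
                    loc, f"weight bounds must lie within {WEIGHT_BOUNDS}"))
        except (ValueError, KeyError, TypeError) as exc:
            failures.append(ValidationFailure(loc, str(exc)))
        pnames.add(pdoc.get("name", f"plast{i}"))
    for i, sdoc in enumerate(doc.get("synapses", [])):
        loc = f"synapses[{i}]"
        w = sdoc.get("weight", 0)
        ws = np.atleast_1d(w)
        if np.any((ws < WEIGHT_BOUNDS[0]) | (ws > WEIGHT_BOUNDS[1])):
            failures.append(ValidationFailure(
                loc, f"weight {w} outside 8-bit range {WEIGHT_BOUNDS}"))
        plast = sdoc.get("plast")
        if isinstance(plast, str) and plast not in pnames:
            failures.append(ValidationFailure(loc, f"dangling plasticity id "
                                                   f"{plast!r}"))
        for end in ("pre", "post"):
            ref = sdoc.get(end)
            if ref is None:
                failures.append(ValidationFailure(loc, f"missing {end!r}"))
            elif isinstance(ref, str):
                base = ref.rsplit(":", 1)[0] if ":" in ref else ref
                if base not in names:
                    failures.append(ValidationFailure(loc, f"dangling group "
                                                           f"reference {ref!r}"))
    cfg = RunConfig(doc=doc)
    return cfg, failures
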