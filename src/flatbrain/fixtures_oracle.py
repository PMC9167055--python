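"""Synthetic benchmark-style models and the interpreted reference simulator.

The generators emulate the three benchmark network families — small
multi-compartment HH cells with event synapses (cerebellar granule-layer
style), Izhikevich point-cell networks with double-exponential synapses
(cortical style), and gap-junction-coupled detailed cells (Golgi-network
style) — plus single-cell and custom-LEMS fixtures. Generation is pure:
the same spec and seed always produce the same document, bit for bit.

:func:`reference_simulate` advances the same models by directly
interpreting the dynamics and compartment structures — no signatures, no
flat tables, no generated code — while following the same integrator tags,
update order, event ordering, rounding contract and RNG streams as the
engine. In full-double mode its recording must equal the engine's bitwise,
which is the package's central correctness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import Recording, hines_core
from .model_analysis import (
    _gate_rate_expr,
    block_eval_phases,
    discretize,
    resolve_attachments,
)
from .nml_io import (
    ComponentInstance,
    EventFileSpec,
    ModelDocument,
    MorphCell,
    OutputFileSpec,
    SimulationSpec,
    eval_expr,
    parse_model_string,
    resolve_probe,
)
from .runtime import f32, f64_identity, neuron_stream, uniform_stream

# --------------------------------------------------------------------------
# Fixture specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # hh_soma | ball_and_stick_net | izhikevich_net | gap_ring |
    #            big_cell | custom_lems
    n: int = 1
    p_connect: float = 0.0
    n_compartments: int = 5
    seed: int = 1


def make_fixture(spec: FixtureSpec) -> ModelDocument:
    if spec.kind == "hh_soma":
        return gen_hh_soma()
    if spec.kind == "ball_and_stick_net":
        return gen_ball_and_stick_net(spec.n, spec.p_connect or 0.2, spec.seed)
    if spec.kind == "izhikevich_net":
        return gen_izhikevich_net(spec.n, spec.p_connect or 0.05, spec.seed)
    if spec.kind == "gap_ring":
        return gen_gap_ring(spec.n, spec.n_compartments)
    if spec.kind == "big_cell":
        return gen_big_cell(spec.n)
    if spec.kind == "custom_lems":
        return gen_custom_lems_cell()
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# squid-axon style channel set (SI rate constants; per_ms units in the XML)
_HH_CHANNELS = """
  <ionChannelHH id="naChan">
    <gateHHrates id="m" instances="3">
      <forwardRate type="HHExpLinearRate" rate="1per_ms" midpoint="-40mV" scale="10mV"/>
      <reverseRate type="HHExpRate" rate="4per_ms" midpoint="-65mV" scale="-18mV"/>
    </gateHHrates>
    <gateHHrates id="h" instances="1">
      <forwardRate type="HHExpRate" rate="0.07per_ms" midpoint="-65mV" scale="-20mV"/>
      <reverseRate type="HHSigmoidRate" rate="1per_ms" midpoint="-35mV" scale="10mV"/>
    </gateHHrates>
  </ionChannelHH>
  <ionChannelHH id="kChan">
    <gateHHrates id="n" instances="4">
      <forwardRate type="HHExpLinearRate" rate="0.1per_ms" midpoint="-55mV" scale="10mV"/>
      <reverseRate type="HHExpRate" rate="0.125per_ms" midpoint="-65mV" scale="-80mV"/>
    </gateHHrates>
  </ionChannelHH>
  <ionChannelHH id="leakChan"/>
"""

# a ~2830 um^2 cylindrical soma (d = L): the 2 nA protocol current lands at
# ~70 uA/cm^2, inside the squid model's repetitive-firing range
_SOMA_D = 30.0


def _soma_segment(seg_id: int = 0) -> str:
    d = _SOMA_D
    return (f'      <segment id="{seg_id}" name="soma">\n'
            f'        <proximal x="0" y="0" z="0" diameter="{d}"/>\n'
            f'        <distal x="{d}" y="0" z="0" diameter="{d}"/>\n'
            f"      </segment>\n")


def _hh_soma_biophysics(extra_groups: str = "soma_group") -> str:
    return f"""
      <membraneProperties>
        <channelDensity id="na" ionChannel="naChan" condDensity="120mS_per_cm2" erev="50mV" segmentGroup="{extra_groups}"/>
        <channelDensity id="k" ionChannel="kChan" condDensity="36mS_per_cm2" erev="-77mV" segmentGroup="{extra_groups}"/>
        <channelDensity id="leak" ionChannel="leakChan" condDensity="0.3mS_per_cm2" erev="-54.3mV" segmentGroup="all"/>
        <spikeThresh value="-20mV"/>
        <specificCapacitance value="1uF_per_cm2" segmentGroup="all"/>
        <initMembPotential value="-65mV"/>
      </membraneProperties>
      <intracellularProperties>
        <resistivity value="100ohm_cm"/>
      </intracellularProperties>
"""


def gen_hh_soma(amplitude_nA: float = 2.0) -> ModelDocument:
    """Single-compartment HH cell with the single-neuron test protocol:
    a DC clamp (default 2 nA) on the soma from 10 to 90 ms."""
    xml = f"""<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="hh">
{_HH_CHANNELS}
  <cell id="hhcell">
    <morphology id="m">
{_soma_segment()}      <segmentGroup id="soma_group">
        <member segment="0"/>
      </segmentGroup>
    </morphology>
    <biophysicalProperties id="bio">{_hh_soma_biophysics()}    </biophysicalProperties>
  </cell>
  <pulseGenerator id="stim" delay="10ms" duration="80ms" amplitude="{amplitude_nA!r}nA"/>
  <network id="net">
    <population id="pop" component="hhcell" size="1"/>
    <inputList id="il0" component="stim" population="pop">
      <input id="0" target="../pop/0/hhcell" segmentId="0"/>
    </inputList>
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def gen_ball_and_stick_net(n: int = 10, p_connect: float = 0.2,
                           seed: int = 1) -> ModelDocument:
    """n four-compartment ball-and-stick cells (HH soma + passive dendrite
    chain), double-exponential event synapses with Bernoulli(p) directed
    connectivity, and Poisson conductance drive on the dendrites."""
    segs = [_soma_segment()]
    x = _SOMA_D
    for i in range(1, 4):
        segs.append(
            f'      <segment id="{i}" name="dend{i}">\n'
            f'        <parent segment="{i - 1}"/>\n'
            f'        <proximal x="{x}" y="0" z="0" diameter="2"/>\n'
            f'        <distal x="{x + 50}" y="0" z="0" diameter="2"/>\n'
            f"      </segment>\n")
        x += 50
    members = "".join(f'        <member segment="{i}"/>\n' for i in range(1, 4))
    rng = np.random.default_rng(seed)
    conns = []
    cid = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rng.random() < p_connect:
                conns.append(
                    f'      <connectionWD id="{cid}" preCellId="../pop/{i}/bscell" '
                    f'postCellId="../pop/{j}/bscell" preSegmentId="0" '
                    f'postSegmentId="0" weight="1" delay="1ms"/>')
                cid += 1
    inputs = []
    iid = 0
    for i in range(n):
        for k in range(5):
            seg = 1 + (k % 3)
            inputs.append(
                f'      <inputW id="{iid}" target="../pop/{i}/bscell" '
                f'segmentId="{seg}" weight="1"/>')
            iid += 1
    xml = f"""<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="bs">
{_HH_CHANNELS}
  <cell id="bscell">
    <morphology id="m">
{"".join(segs)}      <segmentGroup id="soma_group">
        <member segment="0"/>
      </segmentGroup>
      <segmentGroup id="dendrites">
{members}      </segmentGroup>
    </morphology>
    <biophysicalProperties id="bio">{_hh_soma_biophysics()}    </biophysicalProperties>
  </cell>
  <expTwoSynapse id="ampa" gbase="1nS" erev="0mV" tauRise="1ms" tauDecay="5ms"/>
  <poissonFiringSynapse id="drive" averageRate="50Hz" gbase="1.5nS" erev="0mV" tauDecay="5ms"/>
  <network id="net">
    <population id="pop" component="bscell" size="{n}"/>
    <projection id="proj0" synapse="ampa" presynapticPopulation="pop" postsynapticPopulation="pop">
{chr(10).join(conns)}
    </projection>
    <inputList id="il0" component="drive" population="pop">
{chr(10).join(inputs)}
    </inputList>
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def gen_izhikevich_net(n: int = 50, p_connect: float = 0.05,
                       seed: int = 1) -> ModelDocument:
    """Izhikevich point-cell network: regular-spiking and fast-spiking
    populations, double-exponential synapses with fixed connection
    probability (synapse count grows quadratically with n), Poisson drive."""
    n_e = max(1, int(round(0.8 * n)))
    n_i = max(0, n - n_e)
    cells = [("popE", i) for i in range(n_e)] + [("popI", i) for i in range(n_i)]
    rng = np.random.default_rng(seed)
    # one projection per (pre population, post population) pair; excitatory
    # populations project with the AMPA-like synapse, inhibitory with GABA
    projections: dict[tuple[str, str], list[str]] = {}
    cid = 0
    for (pre_pop, pre_i) in cells:
        for (post_pop, post_j) in cells:
            if (pre_pop, pre_i) == (post_pop, post_j):
                continue
            if rng.random() < p_connect:
                projections.setdefault((pre_pop, post_pop), []).append(
                    f'      <connectionWD id="{cid}" '
                    f'preCellId="../{pre_pop}/{pre_i}/x" '
                    f'postCellId="../{post_pop}/{post_j}/x" '
                    f'weight="1" delay="1ms"/>')
                cid += 1
    proj_xml = []
    for pi, ((pre_pop, post_pop), lines) in enumerate(sorted(projections.items())):
        syn = "ampa" if pre_pop == "popE" else "gaba"
        proj_xml.append(
            f'    <projection id="proj{pi}" synapse="{syn}" '
            f'presynapticPopulation="{pre_pop}" '
            f'postsynapticPopulation="{post_pop}">\n'
            + "\n".join(lines) + "\n    </projection>")
    input_lists = []
    iid = 0
    pops_present = [("popE", n_e)] + ([("popI", n_i)] if n_i else [])
    for li, (pop, size) in enumerate(pops_present):
        lines = []
        for i in range(size):
            for _ in range(5):
                lines.append(f'      <inputW id="{iid}" '
                             f'target="../{pop}/{i}/x" weight="1"/>')
                iid += 1
        input_lists.append(
            f'    <inputList id="il{li}" component="drive" population="{pop}">\n'
            + "\n".join(lines) + "\n    </inputList>")
    fs_xml = ('  <izhikevich2007Cell id="fs" v0="-55mV" C="20pF" '
              'k="1nS_per_mV" vr="-55mV" vt="-40mV" vpeak="25mV" '
              'a="0.2per_ms" b="0.2nS" c="-45mV" d="20pA"/>\n') if n_i else ""
    popi_xml = (f'    <population id="popI" component="fs" size="{n_i}"/>\n'
                if n_i else "")
    xml = f"""<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="izh">
  <izhikevich2007Cell id="rs" v0="-60mV" C="100pF" k="0.7nS_per_mV" vr="-60mV"
      vt="-40mV" vpeak="35mV" a="0.03per_ms" b="-2nS" c="-50mV" d="100pA"/>
{fs_xml}  <expTwoSynapse id="ampa" gbase="1nS" erev="0mV" tauRise="0.5ms" tauDecay="3ms"/>
  <expTwoSynapse id="gaba" gbase="2nS" erev="-75mV" tauRise="0.5ms" tauDecay="6ms"/>
  <poissonFiringSynapse id="drive" averageRate="100Hz" gbase="2nS" erev="0mV" tauDecay="3ms"/>
  <network id="net">
    <population id="popE" component="rs" size="{n_e}"/>
{popi_xml}{chr(10).join(proj_xml)}
{chr(10).join(input_lists)}
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def gen_gap_ring(n: int = 4, n_compartments: int = 5) -> ModelDocument:
    """Ring of multi-compartment cells coupled solely through gap junctions
    on their dendrite tips, each driven by 100 Poisson conductance inputs
    spread over the apical dendrites."""
    segs = [_soma_segment()]
    x = _SOMA_D
    for i in range(1, n_compartments):
        segs.append(
            f'      <segment id="{i}" name="dend{i}">\n'
            f'        <parent segment="{i - 1}"/>\n'
            f'        <proximal x="{x}" y="0" z="0" diameter="2"/>\n'
            f'        <distal x="{x + 40}" y="0" z="0" diameter="2"/>\n'
            f"      </segment>\n")
        x += 40
    tip = n_compartments - 1
    gaps = []
    for i in range(n):
        gaps.append(
            f'      <electricalConnectionInstanceW id="{i}" preCell="{i}" '
            f'postCell="{(i + 1) % n}" preSegment="{tip}" postSegment="{tip}" '
            f'weight="1" synapse="gj"/>')
    inputs = []
    iid = 0
    for i in range(n):
        for k in range(100):
            seg = 1 + (k % (n_compartments - 1))
            inputs.append(
                f'      <inputW id="{iid}" target="../pop/{i}/gcell" '
                f'segmentId="{seg}" weight="1"/>')
            iid += 1
    members = "".join(f'        <member segment="{i}"/>\n'
                      for i in range(1, n_compartments))
    xml = f"""<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="gap">
{_HH_CHANNELS}
  <cell id="gcell">
    <morphology id="m">
{"".join(segs)}      <segmentGroup id="soma_group">
        <member segment="0"/>
      </segmentGroup>
      <segmentGroup id="dendrites">
{members}      </segmentGroup>
    </morphology>
    <biophysicalProperties id="bio">{_hh_soma_biophysics()}    </biophysicalProperties>
  </cell>
  <gapJunction id="gj" conductance="500pS"/>
  <poissonFiringSynapse id="drive" averageRate="8Hz" gbase="0.3nS" erev="0mV" tauDecay="5ms"/>
  <network id="net">
    <population id="pop" component="gcell" size="{n}"/>
    <electricalProjection id="eproj" presynapticPopulation="pop" postsynapticPopulation="pop">
{chr(10).join(gaps)}
    </electricalProjection>
    <inputList id="il0" component="drive" population="pop">
{chr(10).join(inputs)}
    </inputList>
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def gen_big_cell(n_comps: int = 319) -> ModelDocument:
    """One detailed cell with three compartment profiles (HH soma, active
    proximal dendrites, passive distal dendrites) — the dedup stress case."""
    n_prox = (n_comps - 1) // 2
    segs = [_soma_segment()]
    x = _SOMA_D
    prox, dist = [], []
    for i in range(1, n_comps):
        segs.append(
            f'      <segment id="{i}" name="d{i}">\n'
            f'        <parent segment="{i - 1}"/>\n'
            f'        <proximal x="{x}" y="0" z="0" diameter="2"/>\n'
            f'        <distal x="{x + 20}" y="0" z="0" diameter="2"/>\n'
            f"      </segment>\n")
        (prox if i <= n_prox else dist).append(i)
        x += 20
    mk = lambda ids: "".join(f'        <member segment="{i}"/>\n' for i in ids)
    xml = f"""<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="big">
{_HH_CHANNELS}
  <cell id="bigcell">
    <morphology id="m">
{"".join(segs)}      <segmentGroup id="soma_group">
        <member segment="0"/>
      </segmentGroup>
      <segmentGroup id="prox">
{mk(prox)}      </segmentGroup>
      <segmentGroup id="dist">
{mk(dist)}      </segmentGroup>
    </morphology>
    <biophysicalProperties id="bio">
      <membraneProperties>
        <channelDensity id="na" ionChannel="naChan" condDensity="120mS_per_cm2" erev="50mV" segmentGroup="soma_group"/>
        <channelDensity id="k" ionChannel="kChan" condDensity="36mS_per_cm2" erev="-77mV" segmentGroup="soma_group"/>
        <channelDensity id="kd" ionChannel="kChan" condDensity="5mS_per_cm2" erev="-77mV" segmentGroup="prox"/>
        <channelDensity id="leak" ionChannel="leakChan" condDensity="0.3mS_per_cm2" erev="-54.3mV" segmentGroup="all"/>
        <spikeThresh value="-20mV"/>
        <specificCapacitance value="1uF_per_cm2" segmentGroup="all"/>
        <initMembPotential value="-65mV"/>
      </membraneProperties>
      <intracellularProperties>
        <resistivity value="100ohm_cm"/>
      </intracellularProperties>
    </biophysicalProperties>
  </cell>
  <network id="net">
    <population id="pop" component="bigcell" size="1"/>
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def gen_custom_lems_cell() -> ModelDocument:
    """A custom LEMS point neuron (leaky integrator with reset), exercising
    the ComponentType parsing path end to end."""
    xml = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="cl">
  <ComponentType name="leakyResetCell" extends="baseCell">
    <Parameter name="rest" dimension="voltage"/>
    <Parameter name="tau" dimension="time"/>
    <Parameter name="thresh" dimension="voltage"/>
    <Parameter name="reset" dimension="voltage"/>
    <Parameter name="drive" dimension="voltage"/>
    <Exposure name="v" dimension="voltage"/>
    <EventPort name="spike" direction="out"/>
    <Dynamics>
      <StateVariable name="v" dimension="voltage"/>
      <DerivedVariable name="vtarget" value="rest + drive"/>
      <TimeDerivative variable="v" value="(vtarget - v) / tau"/>
      <OnStart>
        <StateAssignment variable="v" value="rest"/>
      </OnStart>
      <OnCondition test="v .geq. thresh">
        <StateAssignment variable="v" value="reset"/>
        <EventOut port="spike"/>
      </OnCondition>
    </Dynamics>
  </ComponentType>
  <leakyResetCell id="lcell" rest="-65mV" tau="20ms" thresh="-50mV"
      reset="-70mV" drive="20mV"/>
  <network id="net">
    <population id="pop" component="lcell" size="3"/>
  </network>
</neuroml>
"""
    return parse_model_string(xml)


def default_simulation(doc: ModelDocument, duration: float = 0.1,
                       dt: float = 2.5e-5, seed: int = 12345,
                       record_all: bool = True) -> SimulationSpec:
    """The standard protocol: fixed dt, somatic voltage of every cell
    recorded, plus one spike file over all cells."""
    net = doc.network()
    cols = []
    sels = []
    for p in net.populations:
        cell = doc.cells[p.component]
        if isinstance(cell, ComponentInstance) and cell.spec.kind == "spike_source":
            for i in range(p.size):
                sels.append(f"{p.id}/{i}")
            continue
        for i in range(p.size):
            cols.append(f"{p.id}/{i}/v")
            sels.append(f"{p.id}/{i}")
    spec = SimulationSpec(
        target=net.id, duration=duration, dt=dt, seed=seed,
        output_files=[OutputFileSpec("out.v.dat", cols)],
        event_files=[EventFileSpec("out.spikes", sels)],
    )
    return spec


# --------------------------------------------------------------------------
# Interpreted reference simulator
# --------------------------------------------------------------------------


class _RefSynInst:
    __slots__ = ("weight", "states", "flag", "peer", "u_row", "rate")

    def __init__(self, weight, states, peer=None, u_row=None, rate=None):
        self.weight = weight
        self.states = states
        self.flag = False
        self.peer = peer  # (neuron, comp) for gap junctions
        self.u_row = u_row  # per-step uniforms (poisson elements)
        self.rate = rate


class _RefNeuron:
    pass


def reference_simulate(doc: ModelDocument, sim: SimulationSpec,
                       fp64: bool = False, seed: int | None = None) -> Recording:
    F = f64_identity if fp64 else f32
    seed = sim.seed if seed is None else seed
    net = doc.network(sim.target)
    dt = sim.dt
    n_steps = sim.steps
    attachments = resolve_attachments(doc, net)

    # ---- instantiate neurons
    neurons: list[_RefNeuron] = []
    labels: dict[int, tuple[str, int]] = {}
    pop_offset: dict[str, int] = {}
    for p in net.populations:
        pop_offset[p.id] = len(neurons)
        cell = doc.cells[p.component]
        for i in range(p.size):
            nr = _RefNeuron()
            nr.pop, nr.inst, nr.type_id = p.id, i, p.component
            labels[len(neurons)] = (p.id, i)
            nr.index = len(neurons)
            if isinstance(cell, MorphCell):
                nr.kind = "morph"
                comps = discretize(cell)
                for c in comps:
                    syn, inp = attachments[p.component].get(c.index, ([], []))
                    c.synapse_kinds, c.input_kinds = list(syn), list(inp)
                nr.comps = comps
                nr.parent = [c.parent for c in comps]
                nr.thr = cell.spike_thresh
                nr.cap = [F(c.capacitance) for c in comps]
                nr.gax = [F(c.g_axial) for c in comps]
                nr.chans = []
                nr.v = [F(cell.init_v)] * len(comps)
                nr.gates = []
                for c in comps:
                    cc = []
                    gg = []
                    for (chid, gbar, erev) in c.mechanisms:
                        ch = doc.ion_channels[chid]
                        cc.append((ch, F(gbar), F(erev)))
                        gvals = {}
                        for g in ch.gates:
                            a_, b_, tau, inf = _rates(g, cell.init_v)
                            gvals[g.name] = F(inf)
                        gg.append(gvals)
                    nr.chans.append(cc)
                    nr.gates.append(gg)
                nr.syn = {}
                for c in comps:
                    for kind in c.synapse_kinds + c.input_kinds:
                        nr.syn[(c.index, kind)] = []
            elif cell.spec.kind == "spike_source":
                nr.kind = "source"
                nr.rate = cell.params[cell.spec.poisson_rate_param]
                nr.u = uniform_stream(seed, nr.index, 0, n_steps)
            else:
                nr.kind = "point"
                spec = cell.spec
                nr.spec = spec
                # cell parameters live in (rounded) const slots
                nr.params = {k: F(v) for k, v in cell.params.items()}
                nr.params.update({k: F(v) for k, v in spec.constants.items()})
                env = dict(cell.params)
                env.update(spec.constants)
                init = dict(spec.on_start)
                nr.state = {}
                for s in spec.state_vars:
                    nr.state[s] = F(eval_expr(init[s], env)) if s in init else F(0.0)
                nr.syn = {}
                syn, inp = attachments[p.component].get(0, ([], []))
                nr.kinds = list(syn) + list(inp)
                for kind in nr.kinds:
                    nr.syn[(0, kind)] = []
                nr.rng = None
            neurons.append(nr)

    def kind_spec(kind: str) -> ComponentInstance:
        return doc.synapse_types.get(kind) or doc.input_types[kind]

    def seg_comp(nr: _RefNeuron, seg: int) -> int:
        if nr.kind != "morph":
            return 0
        for c in nr.comps:
            if c.seg_id == seg:
                return c.index
        raise KeyError(seg)

    def new_inst(kind: str, weight: float, peer=None, u_row=None) -> _RefSynInst:
        ks = kind_spec(kind)
        env = dict(ks.params)
        env.update(ks.spec.constants)
        init = dict(ks.spec.on_start)
        states = {}
        for s in ks.spec.state_vars:
            states[s] = F(eval_expr(init[s], env)) if s in init else F(0.0)
        rate = (ks.params[ks.spec.poisson_rate_param]
                if ks.spec.poisson_rate_param else None)
        return _RefSynInst(F(weight), states, peer=peer, u_row=u_row, rate=rate)

    fanout: dict[int, list] = {}
    for conn in net.connections:
        pre = pop_offset[conn.pre_pop] + conn.pre_inst
        post = pop_offset[conn.post_pop] + conn.post_inst
        if conn.electrical:
            pc = seg_comp(neurons[post], conn.post_seg)
            qc = seg_comp(neurons[pre], conn.pre_seg)
            neurons[post].syn[(pc, conn.synapse)].append(
                new_inst(conn.synapse, conn.weight, peer=(pre, qc)))
            neurons[pre].syn[(qc, conn.synapse)].append(
                new_inst(conn.synapse, conn.weight, peer=(post, pc)))
        else:
            pc = seg_comp(neurons[post], conn.post_seg)
            lst = neurons[post].syn[(pc, conn.synapse)]
            lst.append(new_inst(conn.synapse, conn.weight))
            latency = max(1, int(round(conn.delay / dt)))
            fanout.setdefault(pre, []).append(
                (post, pc, conn.synapse, len(lst) - 1, latency))
    for ordinal, ia in enumerate(net.inputs):
        target = pop_offset[ia.population] + ia.instance
        nr = neurons[target]
        c = seg_comp(nr, ia.segment)
        ks = kind_spec(ia.component)
        u_row = (uniform_stream(seed, target, ordinal, n_steps)
                 if ks.spec.poisson_rate_param else None)
        nr.syn[(c, ia.component)].append(
            new_inst(ia.component, ia.weight, u_row=u_row))

    # ---- probes
    probe_paths, probe_loc = [], []
    for of in sim.output_files:
        for col in of.columns:
            tgt = resolve_probe(doc, net, col)
            probe_paths.append(col)
            probe_loc.append((pop_offset[tgt.population] + tgt.instance,
                              tgt.segment, tgt.variable))

    wave = np.zeros((len(probe_paths), n_steps + 1))
    spikes: list[tuple[int, float]] = []
    pending: dict[int, list] = {}

    def read_probe(loc):
        ni, seg, var = loc
        nr = neurons[ni]
        if nr.kind == "morph":
            return nr.v[seg_comp(nr, seg)]
        return nr.state[var]

    _kind_cache: dict[str, tuple] = {}

    def kind_info(kind: str):
        if kind not in _kind_cache:
            ks = kind_spec(kind)
            base_env = dict(ks.params)
            base_env.update(ks.spec.constants)
            const_phase = set(block_eval_phases(ks.spec)[0])
            _kind_cache[kind] = (ks.spec, base_env, const_phase)
        return _kind_cache[kind]

    def block_sum(nr, ci, kind, v_old, t, step, peer_reader):
        """One synapse/input kind on one compartment: event handling,
        per-instance evaluation, current accumulation, state advance —
        identical rounding sequence to the generated table-block loop."""
        spec, base_env, const_phase = kind_info(kind)
        acc = 0.0
        for inst in nr.syn[(ci, kind)]:
            env = dict(base_env)
            env["weight"] = inst.weight
            env["t"] = t
            env["dt"] = dt
            env["v"] = v_old
            for s, val in inst.states.items():
                env[s] = val
            if inst.peer is not None:
                env["vpeer"] = peer_reader(inst.peer)
            for nm, e in spec.derived_vars:
                if nm in const_phase:
                    env[nm] = F(eval_expr(e, env))
            fire = False
            if inst.rate is not None:
                fire = float(inst.u_row[step]) < (inst.rate * dt)
            elif inst.flag:
                fire = True
            if fire and spec.on_events:
                for sv, e in spec.on_events[0].assignments:
                    env[sv] = F(eval_expr(e, env))
            for nm, e in spec.derived_vars:
                if nm not in const_phase:
                    env[nm] = F(eval_expr(e, env))
            acc = F(acc + env["i"]) if "i" in env else acc
            for sv, e in spec.time_derivatives.items():
                inst.states[sv] = F(env[sv] + dt * eval_expr(e, env))
            for sv in spec.state_vars:
                if sv not in spec.time_derivatives:
                    inst.states[sv] = env[sv]
        return acc

    old_v = {ni: (list(nr.v) if nr.kind == "morph" else None)
             for ni, nr in enumerate(neurons)}

    def peer_reader(peer):
        ni, ci = peer
        return old_v[ni][ci]

    # ---- initial recording row
    for pi, loc in enumerate(probe_loc):
        wave[pi, 0] = read_probe(loc)

    for step in range(n_steps):
        t = step * dt
        for (src, ni, ci, kind, idx, _lat) in sorted(pending.pop(step, [])):
            neurons[ni].syn[(ci, kind)][idx].flag = True
        # snapshot of old voltages for gap junctions (previous-step buffer)
        for ni, nr in enumerate(neurons):
            if nr.kind == "morph":
                old_v[ni] = list(nr.v)
        fired = []
        new_states = []
        for nr in neurons:
            if nr.kind == "source":
                f = float(nr.u[step]) < (nr.rate * dt)
                new_states.append(None)
                if f:
                    fired.append(nr.index)
                continue
            if nr.kind == "point":
                spec = nr.spec
                env = dict(nr.params)
                env["t"] = t
                env["dt"] = dt
                for s, val in nr.state.items():
                    env[s] = val
                funcs = _funcs_for(nr, seed)
                isyn = F(0.0)
                v_old = nr.state.get("v", 0.0)
                for kind in nr.kinds:
                    s = block_sum(nr, 0, kind, v_old, t, step, peer_reader)
                    isyn = F(isyn + s)
                if "iSyn" in spec.requirements:
                    env["iSyn"] = isyn
                for nm, e in spec.derived_vars:
                    env[nm] = F(eval_expr(e, env, funcs))
                new = {}
                for s in spec.state_vars:
                    if s in spec.time_derivatives:
                        new[s] = F(env[s] + dt * eval_expr(
                            spec.time_derivatives[s], env, funcs))
                    else:
                        new[s] = env[s]
                env_new = dict(env)
                env_new.update(new)
                did_spike = False
                for oc in spec.on_conditions:
                    if eval_expr(oc.test, env_new, funcs) != 0.0:
                        for sv, e in oc.assignments:
                            new[sv] = F(eval_expr(e, env_new, funcs))
                            env_new[sv] = new[sv]
                        if oc.event_out:
                            did_spike = True
                new_states.append(new)
                if did_spike:
                    fired.append(nr.index)
                continue
            # morphological cell
            n = len(nr.comps)
            GT = [0.0] * n
            GE = [0.0] * n
            II = [0.0] * n
            new_gates = []
            for ci in range(n):
                v = nr.v[ci]
                gtot = F(0.0)
                ge = F(0.0)
                cg = []
                for mi, (ch, gbar, erev) in enumerate(nr.chans[ci]):
                    prod = gbar
                    gnew = {}
                    for g in ch.gates:
                        x = nr.gates[ci][mi][g.name]
                        alpha, beta, tau, inf = _rates(g, v, F)
                        gnew[g.name] = F(inf + ((x - inf)
                                                * math.exp((-dt) / tau)))
                        for _ in range(g.instances):
                            prod = prod * x
                    gch = F(prod)
                    gtot = F(gtot + gch)
                    ge = F(ge + (gch * erev))
                    cg.append(gnew)
                new_gates.append(cg)
                gtot = F(gtot)
                ge = F(ge)
                ii = F(0.0)
                c = nr.comps[ci]
                for kind in c.synapse_kinds + c.input_kinds:
                    s = block_sum(nr, ci, kind, v, t, step, peer_reader)
                    ii = F(ii + s)
                ii = F(ii)
                GT[ci], GE[ci], II[ci] = gtot, ge, ii
            A = [0.0] * n
            Bc = [0.0] * n
            R = [0.0] * n
            for i in range(n):
                A[i] = F(nr.cap[i] / dt + GT[i])
                R[i] = F(nr.cap[i] / dt * old_v[nr.index][i] + GE[i] + II[i])
            for i in range(1, n):
                p_ = nr.parent[i]
                if p_ >= 0:
                    A[i] = F(A[i] + nr.gax[i])
                    A[p_] = F(A[p_] + nr.gax[i])
                    Bc[i] = -nr.gax[i]
            VN = hines_core(A, Bc, R, nr.parent)
            newv = [F(x) for x in VN]
            did_spike = (F(VN[0]) >= nr.thr and old_v[nr.index][0] < nr.thr)
            new_states.append((newv, new_gates))
            if did_spike:
                fired.append(nr.index)
        # commit (write buffer becomes visible only after all items ran)
        for nr, new in zip(neurons, new_states):
            if nr.kind == "point":
                nr.state.update(new)
            elif nr.kind == "morph":
                nr.v, gnew = new
                for ci in range(len(nr.comps)):
                    for mi in range(len(nr.chans[ci])):
                        nr.gates[ci][mi].update(gnew[ci][mi])
        for src in fired:
            for (tgt, ci, kind, idx, latency) in fanout.get(src, []):
                pending.setdefault(step + latency, []).append(
                    (src, tgt, ci, kind, idx, latency))
            spikes.append((src, (step + 1) * dt))
        # consume flags
        for nr in neurons:
            if nr.kind in ("point", "morph"):
                for lst in nr.syn.values():
                    for inst in lst:
                        inst.flag = False
        for pi, loc in enumerate(probe_loc):
            wave[pi, step + 1] = read_probe(loc)

    times = np.arange(n_steps + 1, dtype=np.float64) * dt
    return Recording(times, wave, probe_paths,
                     sorted(spikes, key=lambda x: (x[1], x[0])), labels)


def _funcs_for(nr, seed):
    from .runtime import FUNCTIONS

    def rnd(x):
        if nr.rng is None:
            nr.rng = neuron_stream(seed, nr.index)
        return x * float(nr.rng.random())

    funcs = dict(FUNCTIONS)
    funcs["random"] = rnd
    return funcs


def _rates(gate, v: float, F=lambda x: x):
    """Alpha/beta (or tau/inf) of one gate at voltage v, with the same
    statement-level rounding sequence the generated kernels use."""
    env = {"v": v}
    if gate.mode == "rates":
        alpha = F(eval_expr(_gate_rate_expr(gate.forward, "v"), env))
        beta = F(eval_expr(_gate_rate_expr(gate.reverse, "v"), env))
        tau = F(1.0 / (alpha + beta))
        inf = F(alpha * tau)
        return alpha, beta, tau, inf
    tau = F(gate.tau)
    inf = F(eval_expr(_gate_rate_expr(gate.steady, "v"), env))
    return None, None, tau, inf
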