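"""Kernel emission, integrator selection, loading, numerical behavior."""

import math

import numpy as np
import pytest

import flatbrain as fb
from flatbrain import codegen, errors
from flatbrain.codegen import (
    KernelSource,
    choose_integrator,
    emit_kernel,
    load_kernel,
)
from flatbrain.fixtures_oracle import default_simulation, gen_big_cell, gen_hh_soma
from flatbrain.model_analysis import Update, build_work_plan
from flatbrain.nml_io import parse_expr, parse_model_string

PASSIVE_POINT = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <ComponentType name="passiveCell" extends="baseCell">
    <Parameter name="g" dimension="conductance"/>
    <Parameter name="E" dimension="voltage"/>
    <Parameter name="C" dimension="capacitance"/>
    <Exposure name="v" dimension="voltage"/>
    <Requirement name="iSyn" dimension="current"/>
    <Dynamics>
      <StateVariable name="v" dimension="voltage"/>
      <TimeDerivative variable="v" value="(g * (E - v) + iSyn) / C"/>
      <OnStart><StateAssignment variable="v" value="E"/></OnStart>
    </Dynamics>
  </ComponentType>
  <passiveCell id="pc" g="10nS" E="-65mV" C="100pF"/>
  <pulseGenerator id="dc" delay="0ms" duration="1000ms" amplitude="0.5nA"/>
  <network id="net">
    <population id="pop" component="pc" size="1"/>
    <inputList id="il" component="dc" population="pop">
      <input id="0" target="../pop/0/pc"/>
    </inputList>
  </network>
</neuroml>
"""

FROZEN_GATE_CELL = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <ionChannelHH id="leak"/>
  <ionChannelHH id="naChan">
    <gateHHrates id="m" instances="1">
      <forwardRate type="HHExpLinearRate" rate="1per_ms" midpoint="-40mV" scale="10mV"/>
      <reverseRate type="HHExpRate" rate="4per_ms" midpoint="-65mV" scale="-18mV"/>
    </gateHHrates>
  </ionChannelHH>
  <cell id="fg">
    <morphology id="m">
      <segment id="0" name="soma">
        <proximal x="0" y="0" z="0" diameter="20"/>
        <distal x="20" y="0" z="0" diameter="20"/>
      </segment>
    </morphology>
    <biophysicalProperties id="b">
      <membraneProperties>
        <channelDensity id="l" ionChannel="leak" condDensity="0.3mS_per_cm2" erev="-65mV" segmentGroup="all"/>
        <channelDensity id="na" ionChannel="naChan" condDensity="0mS_per_cm2" erev="50mV" segmentGroup="all"/>
        <specificCapacitance value="1uF_per_cm2" segmentGroup="all"/>
        <initMembPotential value="-65mV"/>
      </membraneProperties>
      <intracellularProperties><resistivity value="100ohm_cm"/></intracellularProperties>
    </biophysicalProperties>
  </cell>
  <network id="net"><population id="pop" component="fg" size="1"/></network>
</neuroml>
"""

GATE_RELAX = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <ComponentType name="gateCell" extends="baseCell">
    <Parameter name="tau" dimension="time"/>
    <Parameter name="inf" dimension="none"/>
    <Parameter name="x0" dimension="none"/>
    <Exposure name="x" dimension="none"/>
    <Dynamics>
      <StateVariable name="x" dimension="none"/>
      <TimeDerivative variable="x" value="(inf - x) / tau"/>
      <OnStart><StateAssignment variable="x" value="x0"/></OnStart>
    </Dynamics>
  </ComponentType>
  <gateCell id="gc" tau="5ms" inf="0.2" x0="0.9"/>
  <network id="net"><population id="pop" component="gc" size="1"/></network>
</neuroml>
"""


class TestChooseIntegrator:
    def test_hh_gate_uses_cnexp(self):
        u = Update("m", None, tau_sym="m_tau", inf_sym="m_inf", is_gate=True)
        assert choose_integrator(u) == "cnexp"

    def test_synapse_state_uses_forward_euler(self):
        u = Update("g", None, deriv=parse_expr("-g/tau"))
        assert choose_integrator(u) == "fwd_euler"

    def test_point_cell_voltage_is_not_a_gate(self):
        u = Update("v", None, deriv=parse_expr("0.04*v*v"))
        assert choose_integrator(u) == "fwd_euler"

    def test_cable_tag_is_preserved(self):
        assert choose_integrator(Update("v", "cable")) == "cable"


class TestEmission:
    def test_izhikevich_kernel_structure(self):
        xml = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <izhikevichCell id="iz" v0="-70mV" a="0.02" b="0.2" c="-65" d="6" thresh="30mV"/>
  <network id="net"><population id="pop" component="iz" size="1"/></network>
</neuroml>"""
        doc = parse_model_string(xml)
        plan = build_work_plan(doc, doc.network())
        src = emit_kernel(plan.types["iz"]).source
        assert "hines" not in src  # point cell: no cable solve
        assert src.count("SW[") >= 2  # two state updates
        assert "V.spike()" in src  # reset handler emits

    def test_hh_soma_gates_cnexp_voltage_cable(self):
        doc = gen_hh_soma()
        plan = build_work_plan(doc, doc.network())
        src = emit_kernel(plan.types["hhcell"]).source
        assert src.count("exp((-dt) /") == 3  # m, h, n via cnexp
        assert "V.hines(" in src  # v via backward-Euler cable path

    def test_regeneration_is_byte_identical(self):
        doc = gen_hh_soma()
        plan = build_work_plan(doc, doc.network())
        a = emit_kernel(plan.types["hhcell"])
        b = emit_kernel(plan.types["hhcell"])
        assert a.source == b.source
        assert a.provenance == b.provenance

    def test_loop_form_statement_count_independent_of_size(self):
        """The dedup-scaling guarantee: statements depend on the number of
        compartment profiles, not on compartment count."""
        counts = {}
        for n in (319, 638):
            doc = gen_big_cell(n)
            plan = build_work_plan(doc, doc.network())
            ns = plan.types["bigcell"]
            assert ns.form == "loop"
            assert len(ns.groups) == 3
            counts[n] = emit_kernel(ns).n_statements
        assert counts[319] == counts[638]


class TestLoadKernel:
    def test_load_and_cache(self):
        src = KernelSource("t", "def kernel(V):\n    pass\n", "kernel", "abc1")
        k1 = load_kernel(src)
        k2 = load_kernel(src)
        assert k1 is k2
        assert callable(k1.fn)

    def test_corrupted_source_raises_generation_bug(self):
        src = KernelSource("t", "def kernel(V:\n    oops\n", "kernel", "bad1")
        with pytest.raises(errors.GenerationBug) as ei:
            load_kernel(src)
        assert "def kernel" in str(ei.value)  # includes a source excerpt

    def test_passive_point_single_step_matches_hand_euler(self):
        """One forward-Euler step: v' = v + dt * (g (E - v) + I) / C."""
        doc = parse_model_string(PASSIVE_POINT)
        sim = default_simulation(doc, duration=2.5e-5)
        eng = fb.Engine(doc, sim, fp64=True)
        eng.step_once()
        g, E, C, I = 10e-9, -65e-3, 100e-12, 0.5e-9
        v0 = E
        expected = v0 + sim.dt * (g * (E - v0) + 1.0 * I * 1.0) / C
        ref = eng.imap.probe_ref("pop", 0, 0, "v")
        assert eng.tset.read(ref, eng.parity) == pytest.approx(expected, rel=1e-12)


class TestIntegratorAccuracy:
    def test_cnexp_matches_closed_form_every_step(self):
        """With constant tau and x_inf, the exponential-Euler update is the
        exact closed form x(t) = x_inf + (x0 - x_inf) e^(-t/tau) at every
        step (checked to binary32 epsilon in full-double mode).

        The gated channel has zero conductance and the leak reversal equals
        the initial potential, so v — and therefore the rates — stays
        exactly constant while the gate relaxes."""
        doc = parse_model_string(FROZEN_GATE_CELL)
        sim = default_simulation(doc, duration=0.02)
        eng = fb.Engine(doc, sim, fp64=True)
        ns = eng.plan.types["fg"]
        off = ns.groups[0].state_slots["ch1_m"]
        _, stt = eng.alloc.type_tables["fg"]
        x0 = 0.9  # push the gate far from steady state
        stt.a[off] = x0
        stt.b[off] = x0
        # constant rates at the resting potential
        from flatbrain.fixtures_oracle import _rates
        cell = doc.cells["fg"]
        ch = doc.ion_channels["naChan"]
        _, _, tau, inf = _rates(ch.gates[0], cell.init_v)
        for k in range(1, 401):
            eng.step_once()
            x = float(stt.buf(eng.parity)[off])
            closed = inf + (x0 - inf) * math.exp(-(k * sim.dt) / tau)
            assert abs(x - closed) <= 4 * np.finfo(np.float32).eps * abs(closed)

    def test_forward_euler_error_is_first_order(self):
        """Halving dt halves the forward-Euler global error (ratio ~2),
        distinguishing it from the exact cnexp update."""
        doc = parse_model_string(GATE_RELAX)
        tau, inf, x0 = 5e-3, 0.2, 0.9
        T = 0.02
        errs = {}
        for dt in (2e-4, 1e-4):
            sim = default_simulation(doc, duration=T, dt=dt)
            sim.output_files[0].columns = ["pop/0/x"]
            eng = fb.Engine(doc, sim, fp64=True)
            rec = eng.run()
            exact = inf + (x0 - inf) * math.exp(-T / tau)
            errs[dt] = abs(rec.waveforms[0][-1] - exact)
        ratio = errs[2e-4] / errs[1e-4]
        assert 1.8 < ratio < 2.2


class TestWriteSet:
    def test_kernel_touches_only_its_own_write_slots(self, izh_doc):
        """Running one work item's kernel leaves every other item's tables
        bit-identical (checksum guard)."""
        sim = default_simulation(izh_doc, duration=2.5e-4)
        eng = fb.Engine(izh_doc, sim, fp64=True)
        item0 = eng.items[0].index
        # snapshot everything
        before = {s: (t.a.copy(), None if t.b is None else t.b.copy())
                  for s, t in eng.tset.tables.items()}
        ctx = eng.ctxs[item0]
        ctx.t, ctx.step = 0.0, 0
        ctx.set_parity(eng.parity)
        eng.kfns[item0](ctx)
        # allowed: item0's state slice (write buffer) + its block tables
        allowed = set()
        ct, stt = eng.alloc.type_tables[eng.plan.items[item0].type_id]
        allowed.add(stt.serial)
        for (item, gi, ki), bt in eng.imap.blocks.items():
            if item == item0:
                allowed.update([bt.st.serial, bt.flag.serial])
        sl = eng.imap.slices
        for s, t in eng.tset.tables.items():
            a0, b0 = before[s]
            if s not in allowed:
                assert np.array_equal(t.a, a0), t.owner
                if t.b is not None:
                    assert np.array_equal(t.b, b0), t.owner
            elif s == stt.serial:
                lo, hi = sl[(item0, s)]
                mask = np.ones(len(t.a), bool)
                mask[lo:hi] = False
                assert np.array_equal(t.b[mask], b0[mask])
                assert np.array_equal(t.a, a0)  # read buffer untouched
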