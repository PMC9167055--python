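"""Compartmentalization, signature construction/merging, deduplication,
and work-plan assembly."""

import math

import pytest

from flatbrain import errors
from flatbrain.fixtures_oracle import gen_big_cell, gen_gap_ring
from flatbrain.model_analysis import (
    Signature,
    Statement,
    build_leaf_signature,
    build_work_plan,
    canonical_identity,
    deduplicate,
    discretize,
    merge_signatures,
    resolve_attachments,
)
from flatbrain.nml_io import Bin, Num, Sym, _builtin, parse_model_string

SPHERE_CELL = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <ionChannelHH id="leak"/>
  <cell id="c">
    <morphology id="m">
      <segment id="0" name="soma">
        <proximal x="0" y="0" z="0" diameter="10"/>
        <distal x="10" y="0" z="0" diameter="10"/>
      </segment>
      <segment id="1" name="dend">
        <parent segment="0"/>
        <proximal x="10" y="0" z="0" diameter="2"/>
        <distal x="60" y="0" z="0" diameter="2"/>
      </segment>
      <segmentGroup id="dendrites"><member segment="1"/></segmentGroup>
    </morphology>
    <biophysicalProperties id="b">
      <membraneProperties>
        <channelDensity id="l" ionChannel="leak" condDensity="0.3mS_per_cm2" erev="-54mV" segmentGroup="dendrites"/>
        <specificCapacitance value="1uF_per_cm2" segmentGroup="all"/>
        <initMembPotential value="-65mV"/>
      </membraneProperties>
      <intracellularProperties><resistivity value="100ohm_cm"/></intracellularProperties>
    </biophysicalProperties>
  </cell>
  <network id="net"><population id="pop" component="c" size="1"/></network>
</neuroml>
"""


class TestDiscretize:
    def test_capacitance_from_cylindrical_surface(self):
        """1 uF/cm^2 on a d = L = 10 um cylinder: C = 1e-2 * pi * (1e-5)^2 F."""
        doc = parse_model_string(SPHERE_CELL)
        comps = discretize(doc.cells["c"])
        assert comps[0].capacitance == pytest.approx(
            1e-2 * math.pi * (1e-5) ** 2, rel=1e-9)

    def test_two_segment_parentage_and_axial(self):
        doc = parse_model_string(SPHERE_CELL)
        comps = discretize(doc.cells["c"])
        assert len(comps) == 2
        assert comps[0].parent == -1
        assert comps[1].parent == 0
        # g = (pi/4) dbar^2 / (Ra L), d = 2 um, L = 50 um, Ra = 1 ohm m
        expected = math.pi / 4 * (2e-6) ** 2 / (1.0 * 50e-6)
        assert comps[1].g_axial == pytest.approx(expected, rel=1e-9)
        assert comps[0].g_axial == 0.0

    def test_group_scoped_density_spares_the_soma(self):
        doc = parse_model_string(SPHERE_CELL)
        comps = discretize(doc.cells["c"])
        assert comps[0].mechanisms == []
        assert len(comps[1].mechanisms) == 1

    def test_missing_biophysics(self):
        doc = parse_model_string(SPHERE_CELL)
        cell = doc.cells["c"]
        cell.densities = []
        cell.specific_capacitance = []
        with pytest.raises(errors.MissingBiophysics):
            discretize(cell)


class TestLeafSignatures:
    def test_exponential_synapse_leaf(self):
        spec = _builtin("expOneSynapse")
        sig = build_leaf_signature(spec, {"gbase": 1e-9, "erev": 0.0,
                                          "tauDecay": 5e-3})
        assert [n for n, _, _ in sig.states] == ["g"]
        assert "v" in sig.requirements
        assert "i" in sig.exposures
        assert len(sig.update_statements) == 1

    def test_stateless_mechanism_has_no_updates(self):
        spec = _builtin("gapJunction")
        sig = build_leaf_signature(spec, {"conductance": 1e-9})
        assert sig.update_statements == []
        assert sig.states == []

    def test_izhikevich_leaf_states(self):
        spec = _builtin("izhikevich2007Cell")
        params = dict(v0=-0.06, k=7e-7, vr=-0.06, vt=-0.04, vpeak=0.035,
                      a=30.0, b=-2e-9, c=-0.05, d=1e-10, C=1e-10)
        sig = build_leaf_signature(spec, params)
        assert [n for n, _, _ in sig.states] == ["v", "u"]
        assert sig.handlers and sig.handlers[0].emits_spike


def _producer(sym_out):
    s = Signature()
    s.eval_statements = [Statement(sym_out, Num(1.0))]
    s.exposures = {sym_out: sym_out}
    return s


def _consumer(sym_in, sym_out):
    s = Signature()
    s.requirements = {sym_in: "none"}
    s.eval_statements = [Statement(sym_out, Bin("+", Sym(sym_in), Num(1.0)))]
    s.exposures = {sym_out: sym_out}
    return s


class TestMergeSignatures:
    def test_topological_ordering_requirements_first(self):
        """A mechanism's requirements are evaluated before the mechanism."""
        parent = Signature()
        parent.eval_statements = [
            Statement("total", Bin("+", Sym("a_y"), Sym("b_y")))]
        ch_a = _consumer("x", "y")  # a needs b's exposure
        ch_b = _producer("y")
        merged = merge_signatures(parent, [("a", ch_a), ("b", ch_b)],
                                  bindings={"a_x": "b_y"})
        order = [s.target for s in merged.eval_statements]
        assert order.index("b_y") < order.index("a_y") < order.index("total")

    def test_document_order_tie_break_is_deterministic(self):
        parent = Signature()
        merged1 = merge_signatures(parent, [("p", _producer("y")),
                                            ("q", _producer("y"))], {})
        merged2 = merge_signatures(parent, [("p", _producer("y")),
                                            ("q", _producer("y"))], {})
        order = [s.target for s in merged1.eval_statements]
        assert order == ["p_y", "q_y"]
        assert order == [s.target for s in merged2.eval_statements]

    def test_unbound_requirement_raises(self):
        parent = Signature()
        with pytest.raises(errors.UnboundRequirement):
            merge_signatures(parent, [("a", _consumer("ghost", "y"))], {})

    def test_cyclic_same_step_dependency_raises(self):
        parent = Signature()
        a = _consumer("x", "y")
        b = _consumer("x", "y")
        with pytest.raises(errors.CyclicExposureDependency):
            merge_signatures(parent, [("a", a), ("b", b)],
                             bindings={"a_x": "b_y", "b_x": "a_y"})

    def test_data_signatures_concatenate_contiguously(self):
        pa = Signature()
        pa.constants = [("c0", "none", 1.0)]
        ca = Signature()
        ca.constants = [("k1", "none", 2.0), ("k2", "none", 3.0)]
        merged = merge_signatures(pa, [("ch", ca)], {})
        assert [n for n, _, _ in merged.constants] == ["c0", "ch_k1", "ch_k2"]

    def test_wellformedness_after_merge(self, bs_doc):
        """Eval-before-use holds for every merged fixture signature."""
        plan = build_work_plan(bs_doc, bs_doc.network())
        for ns in plan.types.values():
            for sig in ns.group_sigs:
                sig.check_wellformed()


class TestDeduplicate:
    def test_three_profiles_partition(self):
        doc = gen_big_cell(319)
        comps = discretize(doc.cells["bigcell"])
        att = resolve_attachments(doc, doc.network())["bigcell"]
        for c in comps:
            syn, inp = att.get(c.index, ([], []))
            c.synapse_kinds, c.input_kinds = list(syn), list(inp)
        groups = deduplicate(comps)
        assert len(groups) == 3
        assert sum(len(g) for g in groups) == 319
        flat = sorted(i for g in groups for i in g)
        assert flat == list(range(319))  # disjoint cover

    def test_all_passive_cell_is_one_group(self):
        doc = parse_model_string(SPHERE_CELL.replace(
            'segmentGroup="dendrites"', 'segmentGroup="all"'))
        comps = discretize(doc.cells["c"])
        assert len(deduplicate(comps)) == 1

    def test_constants_are_data_not_structure(self):
        doc = parse_model_string(SPHERE_CELL.replace(
            'segmentGroup="dendrites"', 'segmentGroup="all"'))
        comps = discretize(doc.cells["c"])
        # same channel kind, very different Gbar (area differs 10x+)
        assert comps[0].mechanisms[0][1] != comps[1].mechanisms[0][1]
        assert canonical_identity(comps[0]) == canonical_identity(comps[1])


class TestResolveAttachments:
    def test_synapse_lands_on_target_compartment_only(self, bs_doc):
        att = resolve_attachments(bs_doc, bs_doc.network())["bscell"]
        assert "ampa" in att[0][0]  # soma compartment, synapse kinds
        assert "ampa" not in att.get(1, ([], []))[0]
        assert "drive" in att[1][1]  # dendrite, input kinds

    def test_gap_junction_attaches_on_both_sides(self, gap_doc):
        att = resolve_attachments(gap_doc, gap_doc.network())["gcell"]
        tip = 4
        assert "gj" in att[tip][0]

    def test_poisson_inputs_on_dendrites(self, gap_doc):
        att = resolve_attachments(gap_doc, gap_doc.network())["gcell"]
        for ci in (1, 2, 3, 4):
            assert "drive" in att[ci][1]


class TestWorkPlan:
    def test_two_populations_enumerate_gapless(self):
        xml = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <izhikevichCell id="iz" v0="-70mV" a="0.02" b="0.2" c="-65" d="6" thresh="30mV"/>
  <network id="net">
    <population id="a" component="iz" size="3"/>
    <population id="b" component="iz" size="2"/>
  </network>
</neuroml>"""
        doc = parse_model_string(xml)
        plan = build_work_plan(doc, doc.network())
        assert [it.index for it in plan.items] == [0, 1, 2, 3, 4]
        assert plan.neuron_index("b", 0) == 3

    def test_heterogeneous_network_has_multiple_kernels(self, izh_doc):
        plan = build_work_plan(izh_doc, izh_doc.network())
        assert len(plan.types) >= 2

    def test_item_count_equals_total_neurons(self, bs_doc):
        plan = build_work_plan(bs_doc, bs_doc.network())
        total = sum(p.size for p in bs_doc.network().populations)
        assert plan.n_neurons == total

    def test_flat_vs_loop_threshold(self, bs_doc):
        plan = build_work_plan(bs_doc, bs_doc.network(), flatten_threshold=8)
        assert plan.types["bscell"].form == "flat"  # 4 compartments <= 8
        plan2 = build_work_plan(bs_doc, bs_doc.network(), flatten_threshold=2)
        assert plan2.types["bscell"].form == "loop"
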