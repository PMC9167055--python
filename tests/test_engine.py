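"""Tree solver and the time-driven loop: double buffering, events,
determinism, numerical safety."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flatbrain as fb
from flatbrain import errors
from flatbrain.engine import CableSystem, Engine, hines_core, hines_solve
from flatbrain.fixtures_oracle import default_simulation
from flatbrain.nml_io import parse_model_string
from tests.conftest import assert_recordings_equal


class TestHines:
    def test_single_node(self):
        assert hines_solve(CableSystem([2.0], [0.0], [4.0], [-1]))[0] == 2.0

    def test_three_node_chain_matches_dense(self):
        a, b, r, parent = [2.0, 2.0, 2.0], [0.0, -1.0, -1.0], [1.0, 0.0, 1.0], [-1, 0, 1]
        dense = np.zeros((3, 3))
        for i in range(3):
            dense[i, i] = a[i]
        for i in (1, 2):
            dense[i, parent[i]] = b[i]
            dense[parent[i], i] = b[i]
        expected = np.linalg.solve(dense, r)
        got = hines_solve(CableSystem(a, b, r, parent))
        assert np.allclose(got, expected, atol=1e-12)

    def test_zero_pivot_raises(self):
        with pytest.raises(errors.SingularSystem):
            hines_core([0.0], [0.0], [1.0], [-1])

    @given(st.integers(2, 50), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=120, deadline=None)
    def test_random_spd_trees_match_dense_solve(self, n, seed):
        """Hines elimination == dense Gaussian elimination on random trees
        with diagonally dominant (SPD) coefficients."""
        rng = np.random.default_rng(seed)
        parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
        b = np.zeros(n)
        b[1:] = -rng.uniform(0.1, 2.0, n - 1)
        a = rng.uniform(0.1, 1.0, n)
        for i in range(1, n):
            a[i] += abs(b[i])
            a[parent[i]] += abs(b[i])
        r = rng.uniform(-1.0, 1.0, n)
        dense = np.diag(a)
        for i in range(1, n):
            dense[i, parent[i]] = b[i]
            dense[parent[i], i] = b[i]
        expected = np.linalg.solve(dense, r)
        got = hines_core(list(a), list(b), list(r), parent)
        assert np.max(np.abs(np.array(got) - expected)) < 1e-6


PASSIVE = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
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

TWO_CELL_SYNAPSE = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <izhikevich2007Cell id="rs" v0="-60mV" C="100pF" k="0.7nS_per_mV" vr="-60mV"
      vt="-40mV" vpeak="35mV" a="0.03per_ms" b="-2nS" c="-50mV" d="100pA"/>
  <expOneSynapse id="syn" gbase="1nS" erev="0mV" tauDecay="5ms"/>
  <pulseGenerator id="dc" delay="5ms" duration="200ms" amplitude="0.3nA"/>
  <network id="net">
    <population id="pop" component="rs" size="2"/>
    <projection id="p" synapse="syn" presynapticPopulation="pop" postsynapticPopulation="pop">
      <connectionWD id="0" preCellId="../pop/0/rs" postCellId="../pop/1/rs" weight="1" delay="0ms"/>
    </projection>
    <inputList id="il" component="dc" population="pop">
      <inputW id="0" target="../pop/0/rs" weight="1"/>
    </inputList>
  </network>
</neuroml>
"""


class TestStepSemantics:
    def test_passive_steady_state_is_E_plus_I_over_g(self):
        """E = -65 mV, g = 10 nS, I = 0.5 nA: v_inf = E + I/g = -15 mV."""
        doc = parse_model_string(PASSIVE)
        sim = default_simulation(doc, duration=0.1)
        rec = Engine(doc, sim, fp64=True).run()
        assert rec.waveforms[0][-1] * 1e3 == pytest.approx(-15.0, abs=0.01)

    def test_hh_rest_stays_near_rest(self, hh_run):
        """HH soma with no stimulus drifts < 1 mV from rest in 100 ms —
        and matches the interpreted oracle."""
        from flatbrain.fixtures_oracle import gen_hh_soma, reference_simulate

        doc = gen_hh_soma(0.0)
        sim = default_simulation(doc, duration=0.1)
        rec = Engine(doc, sim, fp64=True).run()
        ref = reference_simulate(doc, sim, fp64=True)
        assert_recordings_equal(rec, ref)
        v = rec.waveforms[0] * 1e3
        assert np.max(np.abs(v - v[0])) < 1.0

    def test_event_arrives_one_step_after_emission_never_same_step(self):
        """Double-buffer semantics: a presynaptic spike during step k first
        changes the postsynaptic conductance in the state written at k+1."""
        doc = parse_model_string(TWO_CELL_SYNAPSE)
        sim = default_simulation(doc, duration=0.05)
        eng = Engine(doc, sim, fp64=True)
        bt = next(b for b in eng.imap.blocks.values()
                  if b.kind == "syn" and b.n_inst)
        g_trace = []
        spike_step = None
        for s in range(sim.steps):
            eng.step_once()
            g_trace.append(float(bt.st.buf(eng.parity)[0]))
            if eng.fired_last_step and spike_step is None:
                spike_step = s
        assert spike_step is not None, "presynaptic cell never fired"
        assert g_trace[spike_step] == 0.0  # unchanged in the firing step
        assert g_trace[spike_step + 1] > 0.0  # bumped exactly one step later

    def test_run_length_and_determinism(self, hh_doc, protocol_sim):
        """100 ms at 0.025 ms -> 4000 steps (+ initial row); identical
        (model, spec, seed) -> bit-identical recordings."""
        sim = protocol_sim(hh_doc)
        r1 = Engine(hh_doc, sim).run()
        r2 = Engine(hh_doc, sim).run()
        assert len(r1.times) == 4001
        assert_recordings_equal(r1, r2)

    def test_execution_order_never_affects_results(self, izh_doc):
        """Permuting work-item execution order yields bit-identical output —
        the parallelizability contract made testable."""
        sim = default_simulation(izh_doc, duration=0.02)
        base = Engine(izh_doc, sim).run()
        n = sum(p.size for p in izh_doc.network().populations)
        order = list(np.random.default_rng(0).permutation(n))
        perm = Engine(izh_doc, sim).run(exec_order=[int(i) for i in order])
        assert_recordings_equal(base, perm)

    def test_delayed_event_applies_at_exact_step(self):
        doc = parse_model_string(TWO_CELL_SYNAPSE.replace(
            'delay="0ms"', 'delay="2.5ms"'))  # 100 steps at dt = 0.025 ms
        sim = default_simulation(doc, duration=0.06)
        eng = Engine(doc, sim, fp64=True)
        bt = next(b for b in eng.imap.blocks.values()
                  if b.kind == "syn" and b.n_inst)
        first_fire = None
        first_bump = None
        for s in range(sim.steps):
            eng.step_once()
            if eng.fired_last_step and first_fire is None:
                first_fire = s
            if first_bump is None and float(bt.st.buf(eng.parity)[0]) > 0:
                first_bump = s
        assert first_fire is not None
        assert first_bump == first_fire + 100

    def test_charge_balance_sealed_passive_cell(self):
        """A sealed passive cell at its reversal potential holds v constant
        to working precision."""
        doc = parse_model_string(PASSIVE.replace(
            '<inputList component="dc"', "<inputList-disabled").replace(
            '<inputList id="il" component="dc" population="pop">\n'
            '      <input id="0" target="../pop/0/pc"/>\n'
            "    </inputList>", ""))
        sim = default_simulation(doc, duration=0.05)
        rec = Engine(doc, sim).run()
        assert np.all(rec.waveforms[0] == rec.waveforms[0][0])

    def test_numerical_blowup_aborts_with_location(self):
        bad = PASSIVE.replace('C="100pF"', 'C="1e-7pF"')  # dt/tau >> 1
        doc = parse_model_string(bad)
        sim = default_simulation(doc, duration=0.01)
        with pytest.raises(errors.NumericalBlowup) as ei:
            Engine(doc, sim).run()
        assert ei.value.step >= 0
        assert "pc" in ei.value.where


class TestMixedPrecision:
    def test_f32_trace_close_to_f64_and_spikes_within_one_step(
            self, hh_doc, protocol_sim):
        """Single-precision state: somatic voltage within 0.5 mV RMS of the
        full-double run over 100 ms; spike times differ by at most one step."""
        sim = protocol_sim(hh_doc)
        r64 = Engine(hh_doc, sim, fp64=True).run()
        r32 = Engine(hh_doc, sim, fp64=False).run()
        rms = np.sqrt(np.mean((r64.waveforms[0] - r32.waveforms[0]) ** 2))
        assert rms * 1e3 < 0.5
        assert len(r64.spikes) == len(r32.spikes)
        for (_, t64), (_, t32) in zip(r64.spikes, r32.spikes):
            assert abs(t64 - t32) <= sim.dt + 1e-12
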