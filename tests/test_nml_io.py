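"""Reader/writer behavior: units, LEMS dynamics, documents, recordings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flatbrain import errors, nml_io
from flatbrain.nml_io import (
    parse_dynamics,
    parse_expr,
    parse_model_string,
    resolve_probe,
    serialize_model,
    serialize_simulation,
    to_si,
)
from lxml import etree


class TestUnits:
    @pytest.mark.parametrize("text,expected", [
        ("10 mV", 0.010),
        ("0.3 mS_per_cm2", 3.0),
        ("-20mV", -0.020),
        ("1per_ms", 1000.0),
        ("100ohm_cm", 1.0),
        ("1uF_per_cm2", 1e-2),
        ("2nA", 2e-9),
        ("0.7nS_per_mV", 0.7e-6),
        ("5", 5.0),
    ])
    def test_si_conversion(self, text, expected):
        assert to_si(text) == pytest.approx(expected, rel=1e-12)

    def test_unknown_unit_is_an_error(self):
        with pytest.raises(errors.UnknownUnit):
            to_si("3 furlongs")

    def test_dimension_mismatch_at_use_site(self):
        with pytest.raises(errors.DimensionMismatch):
            to_si("10 mV", expect="time")

    @given(st.floats(min_value=1e-12, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_print_parse_round_trip_preserves_magnitude(self, mag):
        q = nml_io.Quantity(mag, "voltage")
        back = nml_io.parse_quantity(str(q))
        assert back.magnitude == pytest.approx(mag, rel=1e-6)
        assert back.dimension == "voltage"


class TestDynamics:
    def _ct(self, body, name="x", extra=""):
        xml = f'<ComponentType name="{name}" extends="baseCell">{extra}<Dynamics>{body}</Dynamics></ComponentType>'
        return parse_dynamics(etree.fromstring(xml))

    def test_leaky_integrator(self):
        spec = self._ct(
            '<StateVariable name="v" dimension="voltage"/>'
            '<TimeDerivative variable="v" value="(rest - v) / tau"/>',
            extra='<Parameter name="rest" dimension="voltage"/>'
                  '<Parameter name="tau" dimension="time"/>'
                  '<Exposure name="v" dimension="voltage"/>')
        assert list(spec.state_vars) == ["v"]
        assert "v" in spec.time_derivatives
        assert "v" in spec.exposures

    def test_derived_variable_cycle_raises(self):
        with pytest.raises(errors.CyclicDerivedVariables):
            self._ct('<DerivedVariable name="a" value="b + 1"/>'
                     '<DerivedVariable name="b" value="a + 1"/>')

    def test_exp_one_synapse_equivalent(self):
        spec = self._ct(
            '<StateVariable name="g" dimension="conductance"/>'
            '<DerivedVariable name="i" value="g * (erev - v)"/>'
            '<TimeDerivative variable="g" value="-g / tau"/>'
            '<OnEvent port="in">'
            '<StateAssignment variable="g" value="g + weight * gbase"/>'
            "</OnEvent>",
            extra='<Parameter name="erev" dimension="voltage"/>'
                  '<Parameter name="tau" dimension="time"/>'
                  '<Parameter name="gbase" dimension="conductance"/>'
                  '<Requirement name="v" dimension="voltage"/>'
                  '<Requirement name="weight" dimension="none"/>'
                  '<EventPort name="in" direction="in"/>')
        assert len(spec.on_events) == 1
        assert len(spec.on_events[0].assignments) == 1
        assert len(spec.time_derivatives) == 1
        # matches the library definition of the exponential synapse
        builtin = nml_io._builtin("expOneSynapse")
        assert builtin.time_derivatives["g"] is not None
        assert len(builtin.on_events[0].assignments) == 1

    def test_unknown_function_raises(self):
        with pytest.raises(errors.UnknownFunction):
            parse_expr("frobnicate(v)")

    def test_kinetic_scheme_is_unsupported(self):
        with pytest.raises(errors.UnsupportedLemsFeature):
            self._ct("<KineticScheme/>")

    @pytest.mark.parametrize("text,env,expected", [
        ("2 + 3 * 4", {}, 14.0),
        ("2 ^ 3 ^ 2", {}, 512.0),  # right-associative power
        ("v .gt. thresh", {"v": 1.0, "thresh": 0.0}, 1.0),
        ("(a .geq. 1) .and. (b .lt. 0)", {"a": 1.0, "b": -1.0}, 1.0),
        ("H(-3)", {}, 0.0),
        ("exp(0) + ln(1)", {}, 1.0),
    ])
    def test_expression_evaluation(self, text, env, expected):
        assert nml_io.eval_expr(parse_expr(text), env) == expected


MINIMAL_IZH = """<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="d">
  <izhikevichCell id="iz" v0="-70mV" a="0.02" b="0.2" c="-65" d="6" thresh="30mV"/>
  <network id="net">
    <population id="pop" component="iz" size="1"/>
  </network>
</neuroml>
"""


class TestParseModel:
    def test_minimal_document(self):
        doc = parse_model_string(MINIMAL_IZH)
        assert len(doc.cells) == 1
        net = doc.network()
        assert len(net.populations) == 1
        assert net.populations[0].size == 1

    def test_undefined_synapse_raises(self):
        xml = MINIMAL_IZH.replace(
            "</network>",
            '<projection id="p" synapse="nope" presynapticPopulation="pop" '
            'postsynapticPopulation="pop">'
            '<connection id="0" preCellId="../pop/0/iz" postCellId="../pop/0/iz"/>'
            "</projection></network>")
        with pytest.raises(errors.UnresolvedReference):
            parse_model_string(xml)

    def test_unsupported_element_raises(self):
        xml = MINIMAL_IZH.replace("<network", "<blorbCell id='x'/><network")
        with pytest.raises(errors.UnsupportedElement):
            parse_model_string(xml)

    def test_notes_are_skipped(self):
        xml = MINIMAL_IZH.replace("<network", "<notes>hi</notes><network")
        assert parse_model_string(xml) is not None

    @pytest.mark.parametrize("kind", [
        "hh_soma", "ball_and_stick_net", "izhikevich_net", "gap_ring",
        "custom_lems",
    ])
    def test_serialize_parse_round_trip(self, kind):
        """parse(serialize(doc)) == doc for every fixture-generated model."""
        from flatbrain.fixtures_oracle import FixtureSpec, make_fixture

        doc = make_fixture(FixtureSpec(kind=kind, n=4, p_connect=0.3, seed=3))
        back = parse_model_string(serialize_model(doc))
        assert back == doc


class TestLoadSimulation:
    def _write(self, tmp_path, doc, sim):
        (tmp_path / "model.nml").write_text(serialize_model(doc))
        lems = tmp_path / "LEMS_sim.xml"
        lems.write_text(serialize_simulation(sim, "model.nml"))
        return lems

    def test_protocol_timing(self, tmp_path, hh_doc, protocol_sim):
        lems = self._write(tmp_path, hh_doc, protocol_sim(hh_doc))
        doc, sim = nml_io.load_simulation(str(lems))
        assert sim.duration == pytest.approx(0.1)
        assert sim.dt == pytest.approx(2.5e-5)
        assert sim.steps == 4000
        assert len(sim.output_files) == 1
        assert len(sim.event_files) == 1

    def test_missing_simulation(self, tmp_path, hh_doc):
        p = tmp_path / "model.nml"
        p.write_text(serialize_model(hh_doc))
        with pytest.raises(errors.MissingSimulation):
            nml_io.load_simulation(str(p))

    def test_bad_probe_path(self, tmp_path, hh_doc, protocol_sim):
        sim = protocol_sim(hh_doc)
        sim.output_files[0].columns.append("pop/7/v")  # instance out of range
        lems = self._write(tmp_path, hh_doc, sim)
        with pytest.raises(errors.UnresolvedProbePath):
            nml_io.load_simulation(str(lems))

    def test_probe_resolution_forms(self, hh_doc):
        net = hh_doc.network()
        a = resolve_probe(hh_doc, net, "pop[0]/v")
        b = resolve_probe(hh_doc, net, "pop/0/v")
        c = resolve_probe(hh_doc, net, "pop/0/hhcell/0/v")
        assert a == b == c

    def test_probe_resolution_injective(self, bs_doc):
        """Distinct probe paths never alias one state slot."""
        from flatbrain.model_analysis import build_work_plan
        from flatbrain.state_tables import Allocation

        net = bs_doc.network()
        plan = build_work_plan(bs_doc, net)
        alloc = Allocation(plan, bs_doc, net)
        refs = list(alloc.imap.probes.values())
        assert len(refs) == len(set(refs))


class TestWriteRecordings:
    def _rec(self, n_steps, n_probes, spikes=()):
        from flatbrain.engine import Recording

        times = np.arange(n_steps + 1) * 1e-3
        waves = np.arange((n_steps + 1) * n_probes, dtype=float).reshape(
            n_probes, n_steps + 1) * 1e-3
        return Recording(times, waves, [f"pop/{i}/v" for i in range(n_probes)],
                         list(spikes), {0: ("pop", 0), 1: ("pop", 1)})

    def _spec(self):
        return nml_io.SimulationSpec(
            target="net", duration=1.0, dt=1e-3,
            output_files=[nml_io.OutputFileSpec("w.dat", ["pop/0/v"])],
            event_files=[nml_io.EventFileSpec("e.spikes", ["pop/0", "pop/1"])],
        )

    def test_shapes(self, tmp_path):
        rec = self._rec(3, 1)
        nml_io.write_recordings(rec, self._spec(), str(tmp_path))
        data = nml_io.read_waveforms(str(tmp_path / "w.dat"))
        assert data.shape == (4, 2)

    def test_empty_spike_train_gives_empty_file(self, tmp_path):
        rec = self._rec(3, 1)
        nml_io.write_recordings(rec, self._spec(), str(tmp_path))
        assert (tmp_path / "e.spikes").read_text() == ""

    def test_write_read_round_trip_exact(self, tmp_path):
        rec = self._rec(5, 1, spikes=[(0, 0.001), (1, 0.004)])
        rec.waveforms[0] = np.array([-0.065, -0.0649, 0.031, -0.02, 1e-7, 0.0])
        nml_io.write_recordings(rec, self._spec(), str(tmp_path))
        data = nml_io.read_waveforms(str(tmp_path / "w.dat"))
        assert np.array_equal(data[:, 0], rec.times)
        assert np.array_equal(data[:, 1], rec.waveforms[0])
        ev = nml_io.read_events(str(tmp_path / "e.spikes"))
        assert ev == [(0, 0.001), (1, 0.004)]

    def test_bit_identical_output(self, tmp_path):
        rec = self._rec(5, 1, spikes=[(0, 0.002)])
        nml_io.write_recordings(rec, self._spec(), str(tmp_path / "a"))
        nml_io.write_recordings(rec, self._spec(), str(tmp_path / "b"))
        assert ((tmp_path / "a" / "w.dat").read_bytes()
                == (tmp_path / "b" / "w.dat").read_bytes())
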