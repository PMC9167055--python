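"""Shared fixtures: generated models and (expensive) simulation runs are
session-scoped so the oracle-equivalence and invariance suites reuse them."""

import numpy as np
import pytest

import flatbrain as fb
from flatbrain import fixtures_oracle as fx


@pytest.fixture(scope="session")
def hh_doc():
    return fx.gen_hh_soma()


@pytest.fixture(scope="session")
def bs_doc():
    return fx.gen_ball_and_stick_net(10, 0.2, 1)


@pytest.fixture(scope="session")
def izh_doc():
    return fx.gen_izhikevich_net(50, 0.05, 1)


@pytest.fixture(scope="session")
def gap_doc():
    return fx.gen_gap_ring(4, 5)


@pytest.fixture(scope="session")
def protocol_sim():
    """The single-neuron protocol timing: 100 ms at dt = 0.025 ms."""
    def make(doc, **kw):
        return fx.default_simulation(doc, duration=0.1, dt=2.5e-5, **kw)
    return make


@pytest.fixture(scope="session")
def hh_run(hh_doc, protocol_sim):
    sim = protocol_sim(hh_doc)
    eng = fb.Engine(hh_doc, sim, fp64=True).run()
    ref = fx.reference_simulate(hh_doc, sim, fp64=True)
    return eng, ref


@pytest.fixture(scope="session")
def fixture_runs(hh_doc, bs_doc, izh_doc, gap_doc, protocol_sim):
    """Engine (full-double) + oracle recordings for every network fixture."""
    out = {}
    for name, doc in [("hh_soma", hh_doc), ("ball_and_stick", bs_doc),
                      ("izhikevich", izh_doc), ("gap_ring", gap_doc)]:
        sim = protocol_sim(doc)
        out[name] = (fb.Engine(doc, sim, fp64=True).run(),
                     fx.reference_simulate(doc, sim, fp64=True))
    return out


def assert_recordings_equal(a, b):
    assert np.array_equal(a.waveforms, b.waveforms), \
        f"waveforms differ, max |d| = {np.max(np.abs(a.waveforms - b.waveforms))}"
    assert a.spikes == b.spikes
    assert np.array_equal(a.times, b.times)
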