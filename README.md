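# flatbrain

A desk-scale, general-purpose neural-network simulator for a documented
NeuroML-v2/LEMS subset, built around *code generation* instead of run-time
model traversal. It is aimed at computational neuroscientists and simulator
developers who want a compact, fully testable implementation of the
compile-the-model architecture: model analysis into code/data signatures,
per-neuron-type kernel generation (with signature deduplication for large
cells), flat table storage with packed table-offset references, a
double-buffered time-driven engine, an emulated multi-worker mode built on
symbolic send lists, and the spike/waveform statistics used to validate one
simulator against another.

## The model and the machinery

Supported models are networks of point neurons (Izhikevich 2003/2007,
integrate-and-fire, adaptive-exponential IaF, arbitrary LEMS ComponentType
dynamics) and multi-compartment cells (HH-style channel densities over
morphological segments), connected by exponential / double-exponential
event synapses and gap junctions, driven by DC pulses and Poisson
conductance inputs.

Numerics: synapse and point-cell states advance by forward Euler; HH gate
variables by exponential Euler (`cnexp`), `x' = x∞ + (x − x∞)e^(−dt/τ)`
with rates frozen over the step; the voltage of compartmental cells by
backward Euler over the cable equation

    (Cᵢ/dt + Σg_chan,ᵢ + Σⱼ g_ij) vᵢ' − Σⱼ g_ij vⱼ' = (Cᵢ/dt) vᵢ + Σ g_chan E + I_syn + I_ext

solved per cell in O(n) by Hines-style tree elimination. State arithmetic
emulates single precision (double precision with `--fp64`); time is always
double.

Every simulation can be cross-checked against an *interpreted reference
simulator* that shares no signature/table/codegen machinery with the
engine; in full-double mode the two must agree **bitwise**, and they do, on
every fixture — as do runs distributed over any number of workers.

## Worked example

Generate a single Hodgkin–Huxley cell with the standard single-neuron
protocol (2 nA DC clamp on the soma from 10 to 90 ms, 100 ms total,
dt = 0.025 ms), run it, and summarize:

```
$ flatbrain fixtures hh_soma --out demo
wrote demo/hh_soma.net.nml
wrote demo/LEMS_hh_soma.xml
$ flatbrain run demo/LEMS_hh_soma.xml --out demo --verbose
wrote demo/out.v.dat
wrote demo/out.spikes
$ flatbrain compare demo/out.v.dat demo/out.v.dat
similarity	1.0
isi_pct_diff	0.0
$ flatbrain netstats demo/out.spikes --duration 0.1
unit	rate_hz	mean_isi_s	local_variation
0	110.0	0.0079275	0.0009236821595764723
```

`out.v.dat` holds 4001 rows (the initial state plus one row per step):
time in seconds, somatic voltage in volts. The cell fires 11 times during
the clamp (110 Hz over the 0.1 s window); the mean inter-spike interval is
7.93 ms and the near-zero local variation says the train is almost
perfectly regular — exactly what a tonically driven HH cell should do.
`similarity` is the NeuroML-DB waveform index
`1 − mean|x−x̂|/(max x − min x)` (1.0 for identical traces) and
`isi_pct_diff` the percent difference in mean ISI at a −20 mV spike
threshold, the two statistics used to compare one simulator's output
against another's.

The same model can be run distributed — results are bit-identical for any
worker count:

```
$ flatbrain run demo/LEMS_hh_soma.xml --out demo --workers 3
```

Library use mirrors the CLI:

```python
import flatbrain as fb
from flatbrain import fixtures_oracle as fx

doc = fx.gen_izhikevich_net(n=50, p_connect=0.05, seed=1)
sim = fx.default_simulation(doc)          # 100 ms at dt = 0.025 ms
rec = fb.run(doc, sim, workers=2)         # bit-identical to workers=1
ref = fx.reference_simulate(doc, sim, fp64=True)  # interpreted oracle
```

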