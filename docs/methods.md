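# Methods

## Overview

flatbrain simulates networks described in a documented NeuroML-v2/LEMS
subset by compiling the model, not interpreting it. Setup proceeds in four
stages:

1. **Model analysis.** The object model is split per neuron type. Each
   morphological cell becomes one compartment per segment; the mechanisms
   declared on segment groups are expanded onto member compartments. Each
   closed-form mechanism (channel gate, synapse kind, input kind) yields a
   *code/data signature*: the ordered evaluation and update statements plus
   the flat list of constants and states they touch. Signatures are merged
   hierarchically — children namespaced, requirements bound to exposures,
   evaluation code topologically ordered so every requirement is defined
   before use (ties broken by document order), data concatenated
   contiguously. Compartments with identical structure (same mechanism
   kinds and attached synapse/input kinds — constants are data, never
   structure) share a *dedup group*.
2. **Code generation.** Each neuron type's signature is emitted as Python
   source and loaded dynamically, cached by signature hash. Cells at or
   under the flattening threshold `K` (default 8 compartments) are fully
   unrolled; larger cells get one loop per dedup group whose iterations
   shift a per-member offset into the group's data slice, so generated
   statement count scales with the number of compartment profiles, not
   compartments.
3. **Instantiation.** All model data lands in flat 1-D tables grouped by
   numeric type and mutability, state tables in two buffers. Scalar slots
   of all instances of a type occupy contiguous slices of type-reserved
   tables; each (work item × dedup group × synapse/input kind) owns a fixed
   set of variable-length tables, extended by one entry per connection.
   Any value is addressable by a packed integer reference
   (`serial << 32 | offset`), and stored references can be redirected
   (e.g. to mirror buffers) without touching generated code.
4. **Simulation.** A fixed-step loop: deliver due spike flags, run every
   work item's kernel (one neuron per work item), collect emitted spikes,
   record probes, swap the state buffers. Work items read only old-step
   state and write only their own slots, so execution order cannot affect
   results — the loop is embarrassingly parallel by construction, and the
   test suite asserts bit-identical output under permuted execution order.

## Numerical methods

- **Point-cell states and synapse states**: forward Euler,
  `x' = x + dt·f(x)`.
- **HH gate variables** (alpha–beta or tau–inf rate dynamics):
  exponential Euler (`cnexp`) with rates frozen at the start-of-step
  voltage, `x' = x∞ + (x − x∞)·e^(−dt/τ)`. With constant rates this is the
  exact solution; the acceptance suite verifies closed-form agreement per
  step and the O(dt) error signature that distinguishes it from forward
  Euler.
- **Membrane voltage of morphological cells** (including single-compartment
  ones): backward Euler over the compartmental cable equation with channel
  conductances frozen at start-of-step gate values:
  `(Cᵢ/dt + Σg_chan,ᵢ + Σⱼg_ij)vᵢ' − Σⱼ g_ij vⱼ' = (Cᵢ/dt)vᵢ + Σg_chan·E + I_syn + I_ext`.
  The tree system is solved by linear-time Gaussian elimination
  (Hines-style: one back-to-front elimination pass, one front-to-back
  substitution pass), verified against dense elimination on random SPD
  trees. This implicit scheme is unconditionally stable, which is why the
  voltage of even one-compartment detailed cells goes through it; point
  cells (Izhikevich, IaF, AdEx, custom LEMS) use their per-state integrator
  tags directly.
- **Geometry**: compartment area is the frustum lateral surface
  (`π·d̄·slant`, sphere `π·d²` for zero-length segments); capacitance is
  specific capacitance × area; axial conductance `(π/4)·d̄²/(Ra·L)`.

### Precision model

The default mode emulates single-precision state arithmetic: expressions
are evaluated in IEEE double, but every *named* assigned variable and every
state store is rounded to binary32, while simulated time and everything
multiplying it stays double. `--fp64` turns the rounding hook into the
identity. Constants stored in table slots (capacitance, conductances,
reversal potentials, weights) round to f32 on instantiation; kind-level
parameters that are identical across instances (synapse time constants,
rate-law coefficients) are inlined into the generated code at full
precision. The interior of the tree solve runs in double; the solution
rounds on store.

### Event semantics

Spike events quantize to steps: arrival step = emission step +
`max(1, round(delay/dt))` — double buffering imposes at least one step of
latency, and sub-step timing is deliberately undefined. On-event
assignments apply to the start-of-step state, so an arriving spike affects
the same step's currents and integration. Event handlers may read
per-instance constants, kind parameters and parameter-only derived
variables (evaluated before event handling — e.g. the double-exponential
synapse's normalization factor); state-dependent derived variables evaluate
after. Multiple spikes converging on one flag in one step OR together;
current accumulation across instances follows a fixed order (group, kind,
then member/document order), which is what makes floating-point sums
reproducible.

Spike detection on detailed cells is an upward crossing of the cell's
declared threshold at the root compartment (`v_old < θ ≤ v_new`); point
cells emit through their LEMS on-condition handlers, whose tests evaluate
over the freshly updated state.

### Randomness

Every stochastic element owns a counter-based (Philox) stream keyed by
`(seed, neuron index, element index)`, where the element index of an input
is its position in the network's input list. Streams are independent of
worker count and execution order. Poisson firing uses a per-step Bernoulli
draw with `p = rate·dt` (for the protocol's `dt` = 25 µs and rates ≤ 100 Hz
the discretization error in the rate is < 0.2%). `random(x)` in LEMS
expressions draws from a per-neuron sequential stream.

## The interpreted oracle

`fixtures_oracle.reference_simulate` is a second, independent simulator: it
walks the dynamics specifications and compartment structures directly —
no signatures, no flat tables, no generated code — while following the same
integrator tags, update order, event ordering, rounding contract and RNG
streams as the engine. Because both paths perform the same arithmetic in
the same order, the engine's recordings must equal the oracle's *bitwise*
(in either precision mode); any divergence in the signature/codegen/table
machinery surfaces as a bit mismatch. This is the package's central
correctness check, and it passes on all fixtures with max |Δ| = 0.

Shared between the two paths are only the ordering/RNG *contracts* and
low-level numerics (the tree solver, rounding hook, rate-law expressions as
data); the signature merge, slot layout, code emission and table machinery
are exercised by the engine alone.

## Multi-worker mode

Neurons are partitioned into contiguous, balanced index ranges. Each worker
instantiates only its own neurons and scans the connection list under four
ownership cases (both local / neither / post-local / pre-local-only).
Cross-worker dependencies become symbolic *send lists* — continuous entries
(gap-junction peer voltages) and spike-event entries — exchanged by a
request/acknowledge/poll handshake in which non-communicating workers
exchange nothing. Continuous dependencies are served by per-peer mirror
tables installed by rewriting the sentinel references left at
instantiation; remote spikes are broadcast to their local recipients on
message arrival. Per step, each worker sends one framed message per
dependent peer: a little-endian u32 payload-length header, a fixed-size
part with state values in send-list order (f32; f64 in `--fp64` mode so the
bitwise checks stay exact), and a variable-size part of freshly fired entry
indices. Mirrors always hold exactly the values a single-worker run would
read from its own previous-step buffer, so recordings are bit-identical for
every worker count — verified for W ∈ {1, 2, 3, 5} on all network fixtures.

The transport is an in-process queue abstraction; a cluster transport would
implement the same three-method surface (`send`/`recv`/counters).

## Synthetic fixtures

The generators emulate the three benchmark network families at desk scale,
plus single-cell cases:

- `hh_soma`: one cylindrical soma (d = L = 30 µm, ~2.8·10⁻⁹ m²) with
  classic squid Na/K/leak channels. The size is chosen so the protocol's
  2 nA clamp lands near 70 µA/cm², inside the model's repetitive-firing
  range (11 spikes over the 80 ms clamp at dt = 25 µs).
- `ball_and_stick_net(n, p, seed)`: n four-compartment cells (HH soma +
  three passive dendrite segments), double-exponential synapses with
  Bernoulli(p) directed connectivity at 1 ms delay, five 50 Hz Poisson
  conductance inputs per cell on the dendrites.
- `izhikevich_net(n, p, seed)`: 80/20 regular-spiking / fast-spiking
  Izhikevich (2007 parameterization) populations, AMPA/GABA-like
  double-exponential synapses with fixed pairwise probability (synapse
  count grows quadratically with n), five 100 Hz Poisson inputs per cell.
- `gap_ring(n, n_comps)`: a ring of detailed cells coupled solely by
  500 pS gap junctions on their dendrite tips, 100 Poisson inputs per cell
  spread over the dendrites (8 Hz, 0.3 nS — sparse, sub-threshold drive).
- `big_cell(n_comps)`: one cell with exactly three compartment profiles
  (HH soma, K-channel proximal dendrites, passive distal dendrites) — the
  dedup-scaling stress case.
- `custom_lems`: a leaky-integrator point neuron defined entirely through a
  LEMS ComponentType, exercising the custom-dynamics parsing path.

Generation is pure: the same spec and seed give byte-identical documents.
What the fixtures do **not** emulate: realistic morphologies (hundreds of
branched segments), heterogeneous per-cell parameters within a population,
NMDA-style voltage-dependent blocking synapses, and the full scale of the
benchmark networks. Passing tests therefore demonstrate the correctness of
the simulation machinery on the supported component set, not biological
fidelity of any particular published model.

Default problem sizes in the test and acceptance suites (n = 10
ball-and-stick cells, n = 50 Izhikevich cells, a 4-cell gap ring, 100 ms at
dt = 0.025 ms) are desk-scale choices that keep the full pipeline — both
execution paths, all worker counts — in a few minutes while leaving every
structural feature (multi-compartment cables, dedup loops, cross-worker
event and graded traffic) exercised.

## Validation metrics

Implemented as in the cross-simulator comparison protocol: the NeuroML-DB
similarity index `1 − mean|x−x̂|/(max x − min x)`; ISI percent difference
(positive = test slower) at a −20 mV detection threshold (upward crossing,
`x[i−1] < θ ≤ x[i]`); per-unit firing rate, mean ISI, and Shinomoto's local
variation `3/(n−1)·Σ((Tᵢ−Tᵢ₊₁)/(Tᵢ+Tᵢ₊₁))²` (0 regular, →1 Poisson; the
exact formula is adopted from the standard definition since the comparison
protocol cites it without printing one); Pearson correlations of spike
counts at a small and a large bin (defaults 2 ms and 100 ms — configurable,
as the protocol does not print its bin widths); the eigenvalue spectrum of
the waveform correlation matrix; and Cohen's d with the 95% CI
`d ± 1.96·√((N₁+N₂)/(N₁N₂) + d²/(2(N₁+N₂−2)))`.

## Known limitations

- LEMS kinetic schemes, regimes, and select/reduce derived variables are
  rejected, not silently ignored; NeuroML v1, SBML and SONATA are out of
  scope.
- One compartment per morphological segment — no `nseg`-style subdivision —
  and no splitting of one neuron across work items or batching of simple
  neurons.
- Fixed time step only; the model structure is frozen once instantiated.
- The generated kernels are Python; the architecture (signature → source →
  dynamically loaded callable, flat tables, table-offset references) is the
  point, not machine-code performance. Hand-optimized kernels could be
  slotted in per neuron type via the kernel cache, but none ship.
- Sub-step event timing is quantized to whole steps by design.
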