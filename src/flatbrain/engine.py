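"""Time-driven simulation engine.

Each step: set the global time, deliver due events (spike flags), execute
every work item's kernel (in any order — results are order-independent by
construction), solve each cell's cable system, record probes, and swap the
state buffers. The engine also exposes the hooks the multi-worker layer
needs: per-step outgoing value/spike collection and incoming mirror/event
application.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codegen
from .errors import NumericalBlowup, SingularSystem
from .model_analysis import WorkPlan, build_work_plan
from .nml_io import (
    ModelDocument,
    SimulationSpec,
    resolve_probe,
)
from .runtime import f32, f64_identity, neuron_stream, uniform_stream
from .state_tables import (
    Allocation,
    append_synapse_entry,
    pack_ref,
    unpack_ref,
)

# --------------------------------------------------------------------------
# Tree-structured linear solver (Hines-equivalent Gaussian elimination)
# --------------------------------------------------------------------------


@dataclass
class CableSystem:
    """Tree-structured symmetric system: diag a, parent off-diag b, rhs r."""

    a: list
    b: list
    r: list
    parent: list


def hines_core(a, b, r, parent):
    """Solve the tree system in one back-to-front elimination and one
    front-to-back substitution pass, O(n). Inputs are not modified."""
    n = len(a)
    a = list(a)
    r = list(r)
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p < 0:
            continue
        if a[i] == 0.0:
            raise SingularSystem(f"zero pivot at node {i}")
        f = b[i] / a[i]
        a[p] -= f * b[i]
        r[p] -= f * r[i]
    if a[0] == 0.0:
        raise SingularSystem("zero pivot at root")
    v = [0.0] * n
    v[0] = r[0] / a[0]
    for i in range(1, n):
        p = parent[i]
        if p < 0:
            if a[i] == 0.0:
                raise SingularSystem(f"zero pivot at node {i}")
            v[i] = r[i] / a[i]
        else:
            v[i] = (r[i] - b[i] * v[p]) / a[i]
    return v


def hines_solve(system: CableSystem):
    """Solve a :class:`CableSystem`; returns the solution vector."""
    return np.asarray(hines_core(system.a, system.b, system.r, system.parent))


# --------------------------------------------------------------------------
# Recording
# --------------------------------------------------------------------------


@dataclass
class Recording:
    times: np.ndarray  # (rows,) f64, t=0 first
    waveforms: np.ndarray  # (probes, rows)
    probe_paths: list[str]
    spikes: list[tuple[int, float]]  # (global neuron index, time_s), sorted
    neuron_labels: dict[int, tuple[str, int]]

    def column(self, path: str) -> np.ndarray:
        return self.waveforms[self.probe_paths.index(path)]


# --------------------------------------------------------------------------
# Kernel execution contexts
# --------------------------------------------------------------------------


class _BlockCtx:
    __slots__ = ("rng", "cst", "st_a", "st_b", "st_r", "st_w", "flag", "ref",
                 "u", "tab")

    def __init__(self, bt):
        self.rng = bt.rng.a
        self.cst = bt.cst.a
        self.st_a = bt.st.a
        self.st_b = bt.st.b
        self.flag = bt.flag.a
        self.ref = bt.ref.a if bt.ref is not None else None
        self.u = bt.u
        self.st_r = self.st_a
        self.st_w = self.st_b


class _ItemCtx:
    """The per-work-item view handed to a kernel (``V`` in generated code)."""

    __slots__ = ("F", "t", "dt", "step", "C", "SR", "SW", "u_src", "_blocks",
                 "_sa", "_sb", "_spiked", "_engine", "_neuron", "_rng",
                 "hines")

    def __init__(self, engine, neuron, C, sa, sb, blocks, u_src):
        self.F = engine.F
        self.dt = engine.dt
        self.t = 0.0
        self.step = 0
        self.C = C
        self._sa = sa
        self._sb = sb
        self.SR = sa
        self.SW = sb
        self.u_src = u_src
        self._blocks = blocks
        self._spiked = False
        self._engine = engine
        self._neuron = neuron
        self._rng = None
        self.hines = hines_core

    def tab(self, gi: int, ki: int) -> _BlockCtx:
        return self._blocks[(gi, ki)]

    def spike(self):
        self._spiked = True

    def deref(self, ref: int) -> float:
        return self._engine.tset.read(ref, self._engine.parity)

    def rand(self, x: float) -> float:
        if self._rng is None:
            self._rng = neuron_stream(self._engine.seed, self._neuron)
        return x * float(self._rng.random())

    def set_parity(self, parity: int):
        if parity == 0:
            self.SR, self.SW = self._sa, self._sb
        else:
            self.SR, self.SW = self._sb, self._sa
        for b in self._blocks.values():
            if parity == 0:
                b.st_r, b.st_w = b.st_a, b.st_b
            else:
                b.st_r, b.st_w = b.st_b, b.st_a


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------


class Engine:
    """Simulates the work items in ``[lo, hi)`` (all of them by default)."""

    def __init__(self, doc: ModelDocument, sim: SimulationSpec, *,
                 fp64: bool = False, seed: int | None = None,
                 lo: int = 0, hi: int | None = None,
                 plan: WorkPlan | None = None,
                 partition=None, worker_id: int = 0,
                 flatten_threshold: int | None = None):
        self.doc = doc
        self.sim = sim
        self.fp64 = fp64
        self.F = f64_identity if fp64 else f32
        self.seed = sim.seed if seed is None else seed
        self.dt = sim.dt
        self.n_steps = sim.steps
        self.net = doc.network(sim.target)
        kw = {}
        if flatten_threshold is not None:
            kw["flatten_threshold"] = flatten_threshold
        self.plan = plan if plan is not None else build_work_plan(
            doc, self.net, **kw)
        self.lo = lo
        self.hi = self.plan.n_neurons if hi is None else hi
        self.partition = partition
        self.worker_id = worker_id
        self.parity = 0
        self.current_step = 0
        self.pending: dict[int, list] = {}
        self.fired_last_step: list[int] = []
        # multi-worker routing (filled by the distributed layer)
        self.cont_requests: dict[int, list] = {}  # peer -> [(loc, sentinel)]
        self.event_requests: dict[int, dict] = {}  # peer -> {loc: [targets]}
        self.mirror_out: dict[int, list] = {}  # peer -> [local refs to send]
        self.event_out: dict[int, list] = {}  # peer -> [local src neurons]
        self.mirror_in: dict[int, object] = {}  # peer -> mirror Table
        self.event_in: dict[int, list] = {}  # peer -> per-entry target lists
        self._setup()

    # -- setup -------------------------------------------------------------

    def _owner(self, neuron: int) -> int:
        if self.partition is None:
            return self.worker_id
        return self.partition.owner(neuron)

    def _local(self, neuron: int) -> bool:
        return self.lo <= neuron < self.hi

    def _setup(self):
        doc, net, plan = self.doc, self.net, self.plan
        self.alloc = Allocation(plan, doc, net, fp64=self.fp64,
                                lo=self.lo, hi=self.hi)
        tset, imap = self.alloc.tset, self.alloc.imap
        self.tset, self.imap = tset, imap
        # synapse instantiation: the four ownership cases
        for conn in net.connections:
            pre = plan.neuron_index(conn.pre_pop, conn.pre_inst)
            post = plan.neuron_index(conn.post_pop, conn.post_inst)
            pre_loc, post_loc = self._local(pre), self._local(post)
            if pre_loc and post_loc:
                append_synapse_entry(self.alloc, conn, self.dt)
            elif not pre_loc and not post_loc:
                continue
            elif conn.electrical:
                # the local side tracks the remote peer's voltage via a
                # sentinel reference, resolved in the fix-up stage
                if post_loc:
                    l_pop, l_inst, l_seg = conn.post_pop, conn.post_inst, conn.post_seg
                    r_pop, r_inst, r_seg = conn.pre_pop, conn.pre_inst, conn.pre_seg
                    r_frac, neuron_l = conn.pre_frac, post
                else:
                    l_pop, l_inst, l_seg = conn.pre_pop, conn.pre_inst, conn.pre_seg
                    r_pop, r_inst, r_seg = conn.post_pop, conn.post_inst, conn.post_seg
                    r_frac, neuron_l = conn.post_frac, pre
                peer = self._owner(plan.neuron_index(r_pop, r_inst))
                sent = self.alloc.next_sentinel()
                comp = self.alloc.comp_of_seg(neuron_l, l_seg)
                self.alloc.add_entry(neuron_l, comp, conn.synapse,
                                     weight=conn.weight, ref=sent)
                self.cont_requests.setdefault(peer, []).append(
                    ((r_pop, r_inst, r_seg, r_frac, "v"), sent))
            elif post_loc:
                # spike from a remote source: instantiate the local
                # mechanism; its flag is set on message arrival
                latency = max(1, int(round(conn.delay / self.dt)))
                comp = self.alloc.comp_of_seg(post, conn.post_seg)
                h = self.alloc.add_entry(post, comp, conn.synapse,
                                         weight=conn.weight,
                                         delay_steps=latency)
                gi, ki, _, _ = self.alloc.block_key(post, comp, conn.synapse)
                peer = self._owner(pre)
                loc = (conn.pre_pop, conn.pre_inst, conn.pre_seg, 0.5, "spike")
                self.event_requests.setdefault(peer, {}).setdefault(
                    loc, []).append((post, gi, ki, h, latency))
            # pre-local-only chemical: skipped; the peer requests our spikes
        # inputs (element ids are the document positions -> RNG stream keys)
        for ordinal, ia in enumerate(net.inputs):
            target = plan.neuron_index(ia.population, ia.instance)
            if not self._local(target):
                continue
            comp = self.alloc.comp_of_seg(target, ia.segment)
            self.alloc.add_entry(target, comp, ia.component,
                                 weight=ia.weight, stream=ordinal)
        self.alloc.finalize()
        # per-step uniforms for stochastic elements
        for (item, gi, ki), bt in imap.blocks.items():
            ns_ = plan.types[plan.items[item].type_id]
            tb = ns_.blocks[gi][ki]
            if tb.poisson_rate is not None:
                rows = [uniform_stream(self.seed, item, int(s), self.n_steps)
                        for s in bt.stream.a] or [np.zeros(0)]
                bt.u = (np.stack(rows) if bt.n_inst
                        else np.zeros((0, self.n_steps)))
        # kernels
        self.kernel_sources = {
            tid: codegen.emit_kernel(ns_) for tid, ns_ in plan.types.items()
        }
        kernels = {tid: codegen.load_kernel(src)
                   for tid, src in self.kernel_sources.items()}
        # item contexts
        self.items = [it for it in plan.items if self._local(it.index)]
        self.ctxs: dict[int, _ItemCtx] = {}
        self.kfns: dict[int, object] = {}
        for it in self.items:
            ns_ = plan.types[it.type_id]
            if ns_.cell_kind == "source":
                u_src = uniform_stream(self.seed, it.index, 0, self.n_steps)
                ctx = _ItemCtx(self, it.index, None, None, None, {}, u_src)
                ctx.SR = ctx.SW = None
            else:
                ct, stt = self.alloc.type_tables[it.type_id]
                cb, sb = self.alloc.item_base[it.index]
                C = ct.a[cb:cb + ns_.n_const]
                sa = stt.a[sb:sb + ns_.n_state]
                sbuf = stt.b[sb:sb + ns_.n_state]
                blocks = {}
                for (item, gi, ki), bt in imap.blocks.items():
                    if item == it.index:
                        blocks[(gi, ki)] = _BlockCtx(bt)
                ctx = _ItemCtx(self, it.index, C, sa, sbuf, blocks, None)
            self.ctxs[it.index] = ctx
            self.kfns[it.index] = kernels[it.type_id].fn
        # probes and spike labels
        self.probe_paths: list[str] = []
        self.probe_refs: list[int | None] = []
        for of in self.sim.output_files:
            for col in of.columns:
                tgt = resolve_probe(doc, net, col)
                self.probe_paths.append(col)
                neuron = plan.neuron_index(tgt.population, tgt.instance)
                if self._local(neuron):
                    self.probe_refs.append(imap.probe_ref(
                        tgt.population, tgt.instance, tgt.segment,
                        tgt.variable))
                else:
                    self.probe_refs.append(None)
        self.neuron_labels = {
            it.index: (it.population, it.instance) for it in plan.items
        }
        self._wave = np.zeros((len(self.probe_paths), self.n_steps + 1))
        self._spikes: list[tuple[int, float]] = []
        self._state_tables = [t for t in tset.tables.values()
                              if t.mutability == "state" and t.dtype == "scalar"]

    # -- stepping ----------------------------------------------------------

    def apply_events(self, due: list):
        """Set the spike flags of all events due this step.

        ``due`` entries are (source neuron, target item, group, kind,
        instance); they are applied in sorted order, and flag writes are
        idempotent, so the outcome is independent of arrival order."""
        for src, titem, gi, ki, idx in sorted(due):
            self.imap.blocks[(titem, gi, ki)].flag.a[idx] = 1

    def _record_row(self, row: int, parity: int):
        for ci, ref in enumerate(self.probe_refs):
            if ref is not None:
                self._wave[ci, row] = self.tset.read(ref, parity)

    def step_once(self, exec_order: list[int] | None = None):
        s = self.current_step
        t = s * self.dt
        due = self.pending.pop(s, [])
        self.apply_events(due)
        order = exec_order if exec_order is not None else [
            it.index for it in self.items
        ]
        for idx in order:
            ctx = self.ctxs[idx]
            ctx.t = t
            ctx.step = s
            ctx.set_parity(self.parity)
            ctx._spiked = False
            self.kfns[idx](ctx)
        # collect spikes in neuron-index order, independent of exec order
        fired = [it.index for it in self.items if self.ctxs[it.index]._spiked]
        for src in fired:
            for (titem, gi, ki, h, latency) in self.imap.fanout.get(src, []):
                self.pending.setdefault(s + latency, []).append(
                    (src, titem, gi, ki, h.index))
            self._spikes.append((src, (s + 1) * self.dt))
        self.fired_last_step = fired
        # consume flags
        for src, titem, gi, ki, idx in due:
            self.imap.blocks[(titem, gi, ki)].flag.a[idx] = 0
        write_parity = 1 - self.parity
        self._record_row(s + 1, write_parity)
        for tb in self._state_tables:
            buf = tb.buf(write_parity)
            if buf.size and not np.isfinite(buf).all():
                bad = int(np.flatnonzero(~np.isfinite(buf))[0])
                raise NumericalBlowup(s, f"{tb.owner}[{bad}]")
        self.parity = write_parity
        self.current_step += 1

    def run(self, exec_order: list[int] | None = None) -> Recording:
        self._record_row(0, self.parity)
        for _ in range(self.n_steps):
            self.step_once(exec_order)
        return self.recording()

    def recording(self) -> Recording:
        times = np.arange(self.n_steps + 1, dtype=np.float64) * self.dt
        return Recording(times, self._wave, list(self.probe_paths),
                         sorted(self._spikes, key=lambda x: (x[1], x[0])),
                         dict(self.neuron_labels))

    # -- multi-worker hooks (used by flatbrain.distributed) ----------------

    def pack_outgoing(self, peer: int) -> tuple[list[float], list[int]]:
        values = [self.tset.read(ref, self.parity)
                  for ref in self.mirror_out.get(peer, [])]
        fired_set = set(self.fired_last_step)
        fired = [i for i, src in enumerate(self.event_out.get(peer, []))
                 if src in fired_set]
        return values, fired

    def apply_incoming(self, peer: int, values: list[float], fired: list[int]):
        mirror = self.mirror_in.get(peer)
        if mirror is not None:
            mirror.a[:len(values)] = values
            mirror.b[:len(values)] = values
        targets = self.event_in.get(peer, [])
        for fi in fired:
            for (titem, gi, ki, h, latency) in targets[fi]:
                self.pending.setdefault(
                    self.current_step + latency - 1, []).append(
                    (-1 - peer, titem, gi, ki, h.index))


def run(doc: ModelDocument, sim: SimulationSpec, workers: int = 1,
        fp64: bool = False, seed: int | None = None) -> Recording:
    """Run a simulation; ``workers > 1`` delegates to the distributed layer
    (results are bit-identical for every worker count)."""
    if workers > 1:
        from .distributed import run_distributed

        return run_distributed(doc, sim, workers, fp64=fp64, seed=seed)
    return Engine(doc, sim, fp64=fp64, seed=seed).run()
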