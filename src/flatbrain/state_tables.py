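"""Flat state storage: typed tables, packed table-offset references,
double-buffered state, and network instantiation into those tables.

Every value of the instantiated model lives in a one-dimensional array
(a *table*), grouped by numeric type and mutability. A value's address packs
the table's serial number into the high bits of an integer and the offset
into the low 32 bits, so generated code can reach any part of the model —
and the references can later be redirected (e.g. to mirror buffers) without
touching the generated code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DanglingSentinel, OffsetOverflow, UnresolvedReference
from .model_analysis import WorkPlan
from .nml_io import ModelDocument, Network, Connection
from .runtime import f32

# --------------------------------------------------------------------------
# Packed references
# --------------------------------------------------------------------------

SENTINEL_SERIAL = 2 ** 31 - 1  # "temporary dummy value" during distributed setup


def pack_ref(serial: int, offset: int) -> int:
    if not (0 <= serial < 2 ** 31):
        raise OffsetOverflow(f"table serial {serial} out of range")
    if not (0 <= offset < 2 ** 32):
        raise OffsetOverflow(f"offset {offset} exceeds 32 bits")
    return (serial << 32) | offset


def unpack_ref(ref: int) -> tuple[int, int]:
    return ref >> 32, ref & 0xFFFFFFFF


def make_sentinel(token: int) -> int:
    """A unique unresolved reference; reading one in debug mode traps."""
    return pack_ref(SENTINEL_SERIAL, token)


def is_sentinel(ref: int) -> bool:
    return (ref >> 32) == SENTINEL_SERIAL


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------


@dataclass
class Table:
    serial: int
    dtype: str  # 'scalar' (f32, f64 in full-double mode) | 'f64' | 'i64'
    mutability: str  # 'const' | 'state'
    a: np.ndarray
    b: np.ndarray | None  # second buffer, state tables only
    owner: str
    holds_refs: bool = False

    def __len__(self) -> int:
        return len(self.a)

    def buf(self, parity: int) -> np.ndarray:
        if self.mutability == "const":
            return self.a
        return self.a if parity == 0 else self.b


class TableSet:
    """All tables of one (worker's part of a) model instance."""

    def __init__(self, fp64: bool = False):
        self.fp64 = fp64
        self.scalar_np = np.float64 if fp64 else np.float32
        self.tables: dict[int, Table] = {}
        self._next_serial = 0

    def new_table(self, dtype: str, mutability: str, length: int,
                  owner: str, holds_refs: bool = False,
                  init: np.ndarray | list | None = None) -> Table:
        np_t = {"scalar": self.scalar_np, "f64": np.float64,
                "i64": np.int64}[dtype]
        a = np.zeros(length, dtype=np_t)
        if init is not None:
            a[:] = init
        b = a.copy() if mutability == "state" else None
        t = Table(self._next_serial, dtype, mutability, a, b, owner, holds_refs)
        self.tables[t.serial] = t
        self._next_serial += 1
        return t

    def read(self, ref: int, parity: int) -> float:
        serial, off = unpack_ref(ref)
        if serial == SENTINEL_SERIAL:
            raise DanglingSentinel(
                f"read of unresolved sentinel reference (token {off})"
            )
        return float(self.tables[serial].buf(parity)[off])

    def swap_noop(self):  # parity is tracked by the engine
        pass

    def total_state_len(self) -> int:
        return sum(len(t) for t in self.tables.values()
                   if t.mutability == "state")

    def buffers_equal(self) -> bool:
        return all(
            t.b is not None and np.array_equal(t.a, t.b, equal_nan=True)
            for t in self.tables.values() if t.mutability == "state"
        )


def redirect_refs(tset: TableSet, mapping: dict[int, int]) -> int:
    """Rewrite stored references equal to a mapping key; returns the count.

    Only tables flagged as reference-holding are scanned; generated code is
    untouched — redirection is purely a data edit.
    """
    if not mapping:
        return 0
    n = 0
    for t in tset.tables.values():
        if not t.holds_refs:
            continue
        for i in range(len(t.a)):
            v = int(t.a[i])
            if v in mapping:
                t.a[i] = mapping[v]
                n += 1
    return n


# --------------------------------------------------------------------------
# Instance map and instantiation
# --------------------------------------------------------------------------


@dataclass
class BlockTables:
    """Concrete tables of one (work item, group, kind) block."""

    role: str
    kind: str
    nc: int  # per-instance const fields
    ns: int  # per-instance state fields
    rng: Table  # i64 const: per member [start, end)
    cst: Table  # scalar const, stride nc
    st: Table  # scalar state, stride ns
    flag: Table  # i64 state: spike flag per instance
    ref: Table | None = None  # i64 const: peer refs (gap junctions)
    stream: Table | None = None  # i64 const: uniform-stream element ids
    delay: Table | None = None  # i64 const: arrival latency in steps
    n_inst: int = 0
    u: np.ndarray | None = None  # per-step uniforms (engine fills)
    p_step: float = 0.0  # per-step firing probability (poisson blocks)


class EntryHandle:
    """Resolves to the entry's final (member-sorted) index after finalize."""

    __slots__ = ("index",)

    def __init__(self):
        self.index = -1


@dataclass
class _BlockBuilder:
    members: int
    nc: int
    ns: int
    role: str
    kind: str
    state_init: list[float]
    rate: float | None
    entries: list = field(default_factory=list)
    # entry: (member, seq, consts, delay_steps, ref, stream, handle)


@dataclass
class InstanceMap:
    slices: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    # ^ (item index, table serial) -> (start, stop)
    probes: dict[tuple[str, int, int, str], int] = field(default_factory=dict)
    # ^ (population, instance, segment, variable) -> packed ref
    blocks: dict[tuple[int, int, int], BlockTables] = field(default_factory=dict)
    fanout: dict[int, list] = field(default_factory=dict)
    # ^ source neuron -> [(target item, gi, ki, EntryHandle, latency_steps)]

    def probe_ref(self, pop: str, inst: int, seg: int, var: str) -> int:
        key = (pop, inst, seg, var)
        if key not in self.probes:
            raise UnresolvedReference(f"no state slot for probe {key}")
        return self.probes[key]


class Allocation:
    """Instantiates (part of) a network into a TableSet + InstanceMap.

    ``lo``/``hi`` bound the owned work items (the single-node case owns all
    of them). Scalar slots of all items of a type live in contiguous slices
    of type-reserved tables; each (item, dedup group, synapse/input kind)
    owns a fixed set of variable-length tables, so the number of tables per
    work item never depends on the instance counts.
    """

    def __init__(self, plan: WorkPlan, doc: ModelDocument, net: Network,
                 fp64: bool = False, lo: int = 0, hi: int | None = None):
        self.plan = plan
        self.doc = doc
        self.net = net
        self.tset = TableSet(fp64)
        self.imap = InstanceMap()
        self.lo = lo
        self.hi = len(plan.items) if hi is None else hi
        self.local_items = [it for it in plan.items if lo <= it.index < self.hi]
        self.type_tables: dict[str, tuple[Table, Table]] = {}
        self.item_base: dict[int, tuple[int, int]] = {}  # item -> (cbase, sbase)
        self._builders: dict[tuple[int, int, int], _BlockBuilder] = {}
        self._seq = 0
        self._sentinel_next = 0
        self._comp_cache: dict[str, list] = {}
        self._alloc_scalars()

    def comps_of(self, type_id: str):
        from .model_analysis import discretize
        from .nml_io import MorphCell

        if type_id not in self._comp_cache:
            cell = self.doc.cells[type_id]
            self._comp_cache[type_id] = (
                discretize(cell) if isinstance(cell, MorphCell) else []
            )
        return self._comp_cache[type_id]

    def comp_of_seg(self, neuron: int, seg: int) -> int:
        comps = self.comps_of(self.plan.items[neuron].type_id)
        for c in comps:
            if c.seg_id == seg:
                return c.index
        if not comps and seg == 0:
            return 0
        raise UnresolvedReference(
            f"segment {seg} not on cell {self.plan.items[neuron].type_id!r}"
        )

    def seg_of_comp(self, neuron: int, comp: int) -> int:
        comps = self.comps_of(self.plan.items[neuron].type_id)
        return comps[comp].seg_id if comps else 0

    # -- scalar slots ------------------------------------------------------

    def _alloc_scalars(self):
        by_type: dict[str, list] = {}
        for it in self.local_items:
            by_type.setdefault(it.type_id, []).append(it)
        for tid, items in by_type.items():
            ns = self.plan.types[tid]
            cdef: list[float] = []
            sdef: list[float] = []
            for g in ns.groups:
                for m in range(len(g.members)):
                    cdef.extend(g.const_defaults[m])
                    sdef.extend(g.state_inits[m])
            n_c, n_s = ns.n_const, ns.n_state
            ct = self.tset.new_table("scalar", "const", n_c * len(items),
                                     f"{tid}.const",
                                     init=np.tile(cdef, len(items)))
            stt = self.tset.new_table("scalar", "state", n_s * len(items),
                                      f"{tid}.state",
                                      init=np.tile(sdef, len(items)))
            self.type_tables[tid] = (ct, stt)
            for k, it in enumerate(items):
                self.item_base[it.index] = (k * n_c, k * n_s)
                self.imap.slices[(it.index, ct.serial)] = (k * n_c, (k + 1) * n_c)
                self.imap.slices[(it.index, stt.serial)] = (k * n_s, (k + 1) * n_s)
        # probe map: segment voltages and point-cell states
        for it in self.local_items:
            ns = self.plan.types[it.type_id]
            if ns.cell_kind == "source":
                continue
            _, stt = self.type_tables[it.type_id]
            _, sbase = self.item_base[it.index]
            if ns.cell_kind == "morph":
                for c in self.comps_of(it.type_id):
                    off = sbase + ns.state_offset(c.index, "v")
                    self.imap.probes[(it.population, it.instance,
                                      c.seg_id, "v")] = pack_ref(stt.serial, off)
            elif ns.cell_kind == "point":
                g = ns.groups[0]
                for sym, off in g.state_slots.items():
                    var = sym[len("cell_"):] if sym.startswith("cell_") else sym
                    self.imap.probes[(it.population, it.instance, 0, var)] = \
                        pack_ref(stt.serial, sbase + off)
        # block builders for every (local item, group, kind)
        for it in self.local_items:
            ns = self.plan.types[it.type_id]
            for gi, g in enumerate(ns.groups):
                for ki, tb in enumerate(ns.blocks[gi]):
                    self._builders[(it.index, gi, ki)] = _BlockBuilder(
                        members=len(g.members),
                        nc=len(tb.const_fields), ns=len(tb.state_fields),
                        role=tb.role, kind=tb.kind,
                        state_init=list(tb.state_init),
                        rate=tb.poisson_rate,
                    )

    # -- entries -----------------------------------------------------------

    def block_key(self, item: int, comp: int, kind: str) -> tuple[int, int, int, int]:
        """Locate (gi, ki, member) of a kind on a compartment of an item."""
        ns = self.plan.types[self.plan.items[item].type_id]
        gi, member = ns.comp_loc[comp]
        for ki, tb in enumerate(ns.blocks[gi]):
            if tb.kind == kind:
                return gi, ki, member, item
        raise UnresolvedReference(
            f"kind {kind!r} not attachable on compartment {comp} of item {item}"
        )

    def add_entry(self, item: int, comp: int, kind: str, *, weight: float,
                  delay_steps: int = 1, ref: int | None = None,
                  stream: int | None = None) -> EntryHandle:
        gi, ki, member, _ = self.block_key(item, comp, kind)
        b = self._builders[(item, gi, ki)]
        h = EntryHandle()
        b.entries.append((member, self._seq, [weight], delay_steps,
                          ref, stream, h))
        self._seq += 1
        return h

    def next_sentinel(self) -> int:
        tok = self._sentinel_next
        self._sentinel_next += 1
        return make_sentinel(tok)

    # -- finalize ----------------------------------------------------------

    def finalize(self):
        """Freeze all block builders into concrete tables.

        Entries are ordered by (member, insertion order) so each member of a
        dedup group owns one contiguous range; insertion order within a
        member is network document order, which fixes the floating-point
        accumulation order once and for all.
        """
        for (item, gi, ki), b in sorted(self._builders.items()):
            entries = sorted(b.entries, key=lambda e: (e[0], e[1]))
            n = len(entries)
            rng_vals = np.zeros(2 * b.members, dtype=np.int64)
            pos = 0
            for m in range(b.members):
                rng_vals[2 * m] = pos
                while pos < n and entries[pos][0] == m:
                    pos += 1
                rng_vals[2 * m + 1] = pos
            owner = f"item{item}.g{gi}.{b.kind}"
            rng_t = self.tset.new_table("i64", "const", 2 * b.members,
                                        owner + ".rng", init=rng_vals)
            cst = np.zeros(n * b.nc)
            st = np.zeros(n * b.ns)
            delay = np.zeros(n, dtype=np.int64)
            refs = np.zeros(n, dtype=np.int64)
            streams = np.zeros(n, dtype=np.int64)
            has_ref = has_stream = False
            for i, (m, _, consts, dsteps, ref, stream, h) in enumerate(entries):
                h.index = i
                cst[i * b.nc:(i + 1) * b.nc] = consts
                st[i * b.ns:(i + 1) * b.ns] = b.state_init
                delay[i] = dsteps
                if ref is not None:
                    refs[i] = ref
                    has_ref = True
                if stream is not None:
                    streams[i] = stream
                    has_stream = True
            bt = BlockTables(
                role=b.role, kind=b.kind, nc=b.nc, ns=b.ns,
                rng=rng_t,
                cst=self.tset.new_table("scalar", "const", n * b.nc,
                                        owner + ".cst", init=cst),
                st=self.tset.new_table("scalar", "state", n * b.ns,
                                       owner + ".st", init=st),
                flag=self.tset.new_table("i64", "state", n, owner + ".flag"),
                n_inst=n,
            )
            bt.delay = self.tset.new_table("i64", "const", n, owner + ".delay",
                                           init=delay)
            if has_ref or b.role == "gap":
                bt.ref = self.tset.new_table("i64", "const", n, owner + ".ref",
                                             holds_refs=True, init=refs)
            if has_stream or b.rate is not None:
                bt.stream = self.tset.new_table("i64", "const", n,
                                                owner + ".stream", init=streams)
            self.imap.blocks[(item, gi, ki)] = bt
        self._builders.clear()


def append_synapse_entry(alloc: Allocation, conn: Connection,
                         dt: float) -> EntryHandle | tuple[EntryHandle, EntryHandle]:
    """Instantiate one (fully local) connection into the tables.

    Chemical synapses extend the post-side mechanism tables by one entry and
    register the pre-side spike source for delivery (arrival latency
    ``max(1, round(delay/dt))`` — double buffering imposes at least one step).
    Gap junctions extend both sides, each holding a packed reference to the
    peer's voltage slot.
    """
    plan, imap = alloc.plan, alloc.imap
    pre = plan.neuron_index(conn.pre_pop, conn.pre_inst)
    post = plan.neuron_index(conn.post_pop, conn.post_inst)
    post_comp = alloc.comp_of_seg(post, conn.post_seg)
    latency = max(1, int(round(conn.delay / dt)))
    if conn.electrical:
        pre_comp = alloc.comp_of_seg(pre, conn.pre_seg)
        ref_pre_v = imap.probe_ref(conn.pre_pop, conn.pre_inst,
                                   conn.pre_seg, "v")
        ref_post_v = imap.probe_ref(conn.post_pop, conn.post_inst,
                                    conn.post_seg, "v")
        h1 = alloc.add_entry(post, post_comp, conn.synapse,
                             weight=conn.weight, ref=ref_pre_v)
        h2 = alloc.add_entry(pre, pre_comp, conn.synapse,
                             weight=conn.weight, ref=ref_post_v)
        return h1, h2
    h = alloc.add_entry(post, post_comp, conn.synapse,
                        weight=conn.weight, delay_steps=latency)
    gi, ki, _, _ = alloc.block_key(post, post_comp, conn.synapse)
    imap.fanout.setdefault(pre, []).append((post, gi, ki, h, latency))
    return h


def dump_tables(tset: TableSet) -> str:
    """Tab-separated manifest: serial, type, mutability, length, owner."""
    lines = ["serial\ttype\tmutability\tlength\towner"]
    for serial in sorted(tset.tables):
        t = tset.tables[serial]
        lines.append(f"{t.serial}\t{t.dtype}\t{t.mutability}\t{len(t)}\t{t.owner}")
    return "\n".join(lines) + "\n"
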