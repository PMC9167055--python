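"""Multi-worker simulation over an in-process transport.

Neurons are split into contiguous index ranges, one per worker. Each worker
instantiates only its own neurons; cross-worker synapses are resolved by the
send-list protocol: every worker scans the connection list, records what it
needs from each peer as a symbolic send list, exchanges those lists with a
request/acknowledge/poll handshake, and installs mirror buffers for the
continuous (gap-junction) dependencies. At run time each worker sends one
framed message per peer per step — a fixed-size part with state values in
send-list order and a variable-size part with the indices of freshly fired
spike sources — and simulation results are bit-identical for every worker
count.
"""

from __future__ import annotations

import struct
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .engine import Engine, Recording
from .errors import DanglingSentinel, FrameLengthMismatch, ProtocolTimeout
from .model_analysis import build_work_plan
from .nml_io import ModelDocument, SimulationSpec
from .state_tables import is_sentinel, pack_ref

# --------------------------------------------------------------------------
# Partitioning
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Contiguous even split of neuron indices over W workers."""

    n: int
    ranges: tuple[tuple[int, int], ...]

    @property
    def w(self) -> int:
        return len(self.ranges)

    def owner(self, neuron: int) -> int:
        for wid, (lo, hi) in enumerate(self.ranges):
            if lo <= neuron < hi:
                return wid
        raise IndexError(neuron)


def partition(n: int, w: int) -> Partition:
    """First ``n mod w`` ranges get ceil(n/w) neurons, the rest floor(n/w)."""
    base = n // w
    extra = n % w
    ranges = []
    lo = 0
    for i in range(w):
        size = base + (1 if i < extra else 0)
        ranges.append((lo, lo + size))
        lo += size
    return Partition(n, tuple(ranges))


# --------------------------------------------------------------------------
# Send lists
# --------------------------------------------------------------------------

Location = tuple[str, int, int, float, str]  # (pop, inst, seg, frac, payload)


@dataclass
class SendList:
    """What one worker needs from one peer, in fixed (wire) order."""

    requester: int
    continuous: list[Location] = field(default_factory=list)
    events: list[Location] = field(default_factory=list)


def build_send_lists(engine: Engine) -> dict[int, SendList]:
    """Assemble this worker's per-peer send lists from the connection scan.

    Entry order is lexicographic over the symbolic location, fixed here once
    and for all — it defines the wire-format indices of the per-step
    messages."""
    lists: dict[int, SendList] = {}
    for peer, reqs in engine.cont_requests.items():
        sl = lists.setdefault(peer, SendList(engine.worker_id))
        sl.continuous = sorted({loc for loc, _ in reqs})
    for peer, reqs in engine.event_requests.items():
        sl = lists.setdefault(peer, SendList(engine.worker_id))
        sl.events = sorted(reqs.keys())
    return lists


# --------------------------------------------------------------------------
# Transport (in-process queues; the adapter surface a real MPI transport
# would implement: send / recv / pending)
# --------------------------------------------------------------------------


class InProcTransport:
    def __init__(self, w: int):
        self.w = w
        self.queues: dict[tuple[int, int], deque] = {
            (i, j): deque() for i in range(w) for j in range(w)
        }
        self.n_messages = 0
        self.bytes_sent = 0

    def send(self, src: int, dst: int, payload):
        self.queues[(src, dst)].append(payload)
        self.n_messages += 1
        if isinstance(payload, (bytes, bytearray)):
            self.bytes_sent += len(payload)

    def recv(self, src: int, dst: int):
        q = self.queues[(src, dst)]
        if not q:
            return None
        return q.popleft()


# --------------------------------------------------------------------------
# Send-list exchange (request / ack / completion poll)
# --------------------------------------------------------------------------


@dataclass
class ExchangeStats:
    requests: int = 0
    acks: int = 0
    poll_rounds: int = 0


def exchange_send_lists(engines: list[Engine], transport: InProcTransport,
                        max_rounds: int = 1000) -> ExchangeStats:
    """Exchange send lists among workers.

    Each worker sends one request (containing its send list) to every peer
    it needs data from and awaits an acknowledgement; all workers poll until
    every request has been acknowledged. Workers with no mutual dependency
    exchange nothing. After the exchange every sender knows its outgoing
    lists (``mirror_out`` refs and ``event_out`` sources, in wire order).
    """
    stats = ExchangeStats()
    want: dict[int, dict[int, SendList]] = {}
    outstanding: dict[int, set[int]] = {}
    for e in engines:
        lists = build_send_lists(e)
        want[e.worker_id] = lists
        outstanding[e.worker_id] = set(lists)
        for peer, sl in lists.items():
            transport.send(e.worker_id, peer, ("req", sl))
            stats.requests += 1
    by_id = {e.worker_id: e for e in engines}
    done = False
    rounds = 0
    while not done:
        rounds += 1
        if rounds > max_rounds:
            raise ProtocolTimeout("send-list exchange did not terminate")
        progress = False
        for e in engines:
            for src in range(transport.w):
                while True:
                    msg = transport.recv(src, e.worker_id)
                    if msg is None:
                        break
                    progress = True
                    tag, payload = msg
                    if tag == "req":
                        _serve_request(e, payload)
                        transport.send(e.worker_id, src, ("ack", None))
                        stats.acks += 1
                    elif tag == "ack":
                        outstanding[e.worker_id].discard(src)
        stats.poll_rounds += 1
        done = all(not v for v in outstanding.values())
        if not progress and not done:
            raise ProtocolTimeout("send-list exchange deadlocked")
    return stats


def _serve_request(sender: Engine, sl: SendList):
    """The sender resolves a peer's symbolic send list to local slots."""
    refs = []
    for (pop, inst, seg, _frac, var) in sl.continuous:
        refs.append(sender.imap.probe_ref(pop, inst, seg, var))
    sender.mirror_out[sl.requester] = refs
    sources = []
    for (pop, inst, _seg, _frac, _payload) in sl.events:
        sources.append(sender.plan.neuron_index(pop, inst))
    sender.event_out[sl.requester] = sources


# --------------------------------------------------------------------------
# Mirror installation / synapse fix-up
# --------------------------------------------------------------------------


def install_mirrors(engine: Engine):
    """Allocate one mirror table per sending peer and rewrite the sentinel
    references of cross-worker graded synapses to point at it; wire remote
    event entries to their local spike-recipient targets."""
    from .state_tables import redirect_refs

    lists = build_send_lists(engine)
    for peer, sl in lists.items():
        if sl.continuous:
            mirror = engine.tset.new_table(
                "scalar", "state", len(sl.continuous),
                f"mirror.from{peer}")
            engine.mirror_in[peer] = mirror
            idx_of = {loc: i for i, loc in enumerate(sl.continuous)}
            mapping = {}
            for loc, sentinel in engine.cont_requests.get(peer, []):
                mapping[sentinel] = pack_ref(mirror.serial, idx_of[loc])
            redirect_refs(engine.tset, mapping)
        if sl.events:
            reqs = engine.event_requests.get(peer, {})
            engine.event_in[peer] = [reqs.get(loc, []) for loc in sl.events]
    # every sentinel must have been fixed up
    for t in engine.tset.tables.values():
        if t.holds_refs:
            for v in t.a:
                if is_sentinel(int(v)):
                    raise DanglingSentinel(
                        f"unresolved sentinel left in {t.owner}"
                    )


# --------------------------------------------------------------------------
# Run-time messages
# --------------------------------------------------------------------------


@dataclass
class Message:
    values: list[float]
    fired: list[int]


def pack_message(values: list[float], fired: list[int],
                 fp64: bool = False) -> bytes:
    """Frame one per-step message: u32 payload length header, fixed-size
    state-value part, variable-size fired-index part (little-endian)."""
    fmt = "d" if fp64 else "f"
    payload = struct.pack(f"<{len(values)}{fmt}", *values)
    payload += struct.pack(f"<{len(fired)}i", *fired)
    return struct.pack("<I", len(payload)) + payload


def unpack_message(data: bytes, n_continuous: int,
                   fp64: bool = False) -> Message:
    if len(data) < 4:
        raise FrameLengthMismatch("missing header")
    (length,) = struct.unpack_from("<I", data, 0)
    payload = data[4:]
    if len(payload) != length:
        raise FrameLengthMismatch(
            f"header says {length} bytes, got {len(payload)}"
        )
    vsize = 8 if fp64 else 4
    fixed = n_continuous * vsize
    if fixed > length or (length - fixed) % 4:
        raise FrameLengthMismatch(
            f"payload of {length} bytes cannot hold {n_continuous} values"
        )
    fmt = "d" if fp64 else "f"
    values = list(struct.unpack_from(f"<{n_continuous}{fmt}", payload, 0))
    n_fired = (length - fixed) // 4
    fired = list(struct.unpack_from(f"<{n_fired}i", payload, fixed))
    if any(b < a for a, b in zip(fired, fired[1:])):
        raise FrameLengthMismatch("fired indices not increasing")
    return Message(values, fired)


# --------------------------------------------------------------------------
# Distributed run
# --------------------------------------------------------------------------


def run_distributed(doc: ModelDocument, sim: SimulationSpec, workers: int,
                    fp64: bool = False, seed: int | None = None,
                    transport: InProcTransport | None = None) -> Recording:
    """Simulate with ``workers`` cooperating in-process workers.

    Communication only relocates reads (mirrors hold exactly the values a
    single-worker run would read from its own buffers), so the merged
    recording is bit-identical to ``Engine.run`` for every worker count.
    """
    net = doc.network(sim.target)
    plan = build_work_plan(doc, net)
    part = partition(plan.n_neurons, workers)
    transport = transport or InProcTransport(workers)
    engines = [
        Engine(doc, sim, fp64=fp64, seed=seed, plan=plan,
               lo=lo, hi=hi, partition=part, worker_id=wid)
        for wid, (lo, hi) in enumerate(part.ranges)
    ]
    exchange_send_lists(engines, transport)
    for e in engines:
        install_mirrors(e)
    recv_peers = {
        e.worker_id: sorted(set(e.cont_requests) | set(e.event_requests))
        for e in engines
    }
    n_cont = {
        e.worker_id: {p: len(sl.continuous)
                      for p, sl in build_send_lists(e).items()}
        for e in engines
    }
    for e in engines:
        e._record_row(0, e.parity)
    for _ in range(sim.steps):
        # send early ...
        for e in engines:
            for peer in sorted(set(e.mirror_out) | set(e.event_out)):
                values, fired = e.pack_outgoing(peer)
                transport.send(e.worker_id, peer,
                               pack_message(values, fired, fp64))
        # ... receive, then compute
        for e in engines:
            for peer in recv_peers[e.worker_id]:
                data = transport.recv(peer, e.worker_id)
                if data is None:
                    raise ProtocolTimeout(
                        f"worker {e.worker_id} missing message from {peer}"
                    )
                msg = unpack_message(data, n_cont[e.worker_id].get(peer, 0),
                                     fp64)
                e.apply_incoming(peer, msg.values, msg.fired)
        for e in engines:
            e.step_once()
    # merge per-worker recordings
    recs = [e.recording() for e in engines]
    base = recs[0]
    wave = np.zeros_like(base.waveforms)
    for ci in range(len(base.probe_paths)):
        for e, r in zip(engines, recs):
            if e.probe_refs[ci] is not None:
                wave[ci] = r.waveforms[ci]
                break
    spikes = sorted((s for r in recs for s in r.spikes),
                    key=lambda x: (x[1], x[0]))
    return Recording(base.times, wave, base.probe_paths, spikes,
                     base.neuron_labels)
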