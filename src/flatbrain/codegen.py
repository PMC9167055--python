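"""Kernel generation: neuron-type signatures to executable source.

Kernels are emitted as host-language (Python) source and loaded dynamically,
preserving the architectural contract signature -> source -> loaded callable.
Regenerating from the same signature yields byte-identical source, and the
loader caches kernels by signature hash.

Calling contract: ``kernel(V)`` where ``V`` is the per-work-item view the
engine provides (const/state slices, per-block tables, time, dt, rounding
hook, tree solver, RNG streams). A kernel reads old-step state only from the
read buffers and writes only its own write-buffer slots; spikes are signaled
through ``V.spike()`` and routed by the engine under the deterministic
ordered-accumulation contract.
"""

from __future__ import annotations

import hashlib
import keyword
import math
from dataclasses import dataclass

from .errors import GenerationBug
from .model_analysis import (
    NeuronSignature,
    Signature,
    Statement,
    TableBlock,
    Update,
)
from .nml_io import render_py
from .runtime import FUNCTIONS


def choose_integrator(update: Update, context: Signature | None = None) -> str:
    """Integrator tag for one state variable.

    ``cnexp`` (exponential Euler with rates frozen over the step) applies
    exactly to HH gate variables with alpha-beta or tau-inf dynamics; the
    membrane voltage of morphological cells goes through the backward-Euler
    cable solve; everything else (synapse states, point-cell dynamics) uses
    forward Euler.
    """
    if update.method == "cable":
        return "cable"
    if update.is_gate and update.tau_sym and update.inf_sym:
        return "cnexp"
    return "fwd_euler"


@dataclass(frozen=True)
class KernelSource:
    type_id: str
    source: str
    entry: str
    provenance: str  # signature hash

    @property
    def n_statements(self) -> int:
        return sum(1 for line in self.source.splitlines()
                   if line.strip() and not line.strip().startswith("#"))


@dataclass
class Kernel:
    fn: object
    provenance: str
    source: KernelSource


def _mangle(name: str) -> str:
    if name in ("t", "dt"):
        return name
    if keyword.iskeyword(name):
        return f"x_k_{name}"
    return f"x_{name}"


def _r(expr) -> str:
    return render_py(expr, rename=_mangle)


class _Emitter:
    def __init__(self):
        self.lines: list[str] = []

    def w(self, indent: int, text: str):
        self.lines.append("    " * indent + text)

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _emit_block(em: _Emitter, ind: int, gi: int, ki: int, tb: TableBlock,
                member_expr: str):
    """Per-instance loop of one synapse/input kind on one compartment."""
    nc, ns = len(tb.const_fields), len(tb.state_fields)
    em.w(ind, f"TB = V.tab({gi}, {ki})")
    em.w(ind, f"_s = int(TB.rng[2 * {member_expr}]); _e = int(TB.rng[2 * {member_expr} + 1])")
    em.w(ind, "_acc = 0.0")
    em.w(ind, "for _k in range(_s, _e):")
    b = ind + 1
    for fi, fname in enumerate(tb.const_fields):
        em.w(b, f"{_mangle(fname)} = float(TB.cst[_k * {nc} + {fi}])")
    for fi, fname in enumerate(tb.state_fields):
        em.w(b, f"{_mangle(fname)} = float(TB.st_r[_k * {ns} + {fi}])")
    if tb.uses_peer:
        em.w(b, f"{_mangle('vpeer')} = V.deref(int(TB.ref[_k]))")
    for s in tb.pre_evals:  # parameter-only phase: visible to event handlers
        em.w(b, f"{_mangle(s.target)} = F({_r(s.expr)})")
    if tb.poisson_rate is not None:
        em.w(b, f"if float(TB.u[_k, V.step]) < ({tb.poisson_rate!r} * dt):")
        for sv, e in tb.on_event:
            em.w(b + 1, f"{_mangle(sv)} = F({_r(e)})")
    elif tb.on_event:
        em.w(b, "if TB.flag[_k] != 0:")
        for sv, e in tb.on_event:
            em.w(b + 1, f"{_mangle(sv)} = F({_r(e)})")
    for s in tb.evals:
        em.w(b, f"{_mangle(s.target)} = F({_r(s.expr)})")
    em.w(b, f"_acc = F(_acc + {_mangle(tb.instance_current)})")
    for u in tb.updates:
        fi = tb.state_fields.index(u.state)
        em.w(b, f"TB.st_w[_k * {ns} + {fi}] = "
                f"F({_mangle(u.state)} + dt * ({_r(u.deriv)}))")
    written = {u.state for u in tb.updates}
    for fi, fname in enumerate(tb.state_fields):
        if fname not in written:  # carry unmodified state into the new buffer
            em.w(b, f"TB.st_w[_k * {ns} + {fi}] = {_mangle(fname)}")
    em.w(ind, f"{_mangle(tb.accum_sym)} = _acc")


def _emit_member_body(em: _Emitter, ind: int, sig: Signature, gi: int,
                      ns_: NeuronSignature, coff, soff, member_expr: str,
                      comp_expr: str | None):
    """Eval + update code for one compartment (or one point cell).

    ``coff``/``soff`` map a slot symbol to a const/state index expression;
    ``comp_expr`` (morph cells) indexes the per-compartment assembly arrays.
    """
    for n, _, _ in sig.constants:
        em.w(ind, f"{_mangle(n)} = float(C[{coff(n)}])")
    for n, _, _ in sig.states:
        em.w(ind, f"{_mangle(n)} = float(SR[{soff(n)}])")
    ki_of = {id(tb): ki for ki, tb in enumerate(ns_.blocks[gi])}
    for item in sig.eval_statements:
        if isinstance(item, TableBlock):
            _emit_block(em, ind, gi, ki_of[id(item)], item, member_expr)
        else:
            em.w(ind, f"{_mangle(item.target)} = F({_r(item.expr)})")
    if comp_expr is not None:
        em.w(ind, f"VV[{comp_expr}] = {_mangle('v')}")
        em.w(ind, f"CAP[{comp_expr}] = {_mangle('cap')}")
        em.w(ind, f"GAX[{comp_expr}] = {_mangle('gax')}")
        em.w(ind, f"GT[{comp_expr}] = {_mangle('gtot')}")
        em.w(ind, f"GE[{comp_expr}] = {_mangle('ge')}")
        em.w(ind, f"II[{comp_expr}] = {_mangle('icur')}")
    for u in sig.update_statements:
        method = choose_integrator(u)
        if method == "cable":
            continue
        tgt = f"SW[{soff(u.state)}]"
        if method == "cnexp":
            em.w(ind, f"{tgt} = F({_mangle(u.inf_sym)} + "
                      f"(({_mangle(u.state)} - {_mangle(u.inf_sym)}) * "
                      f"exp((-dt) / {_mangle(u.tau_sym)})))")
        else:
            em.w(ind, f"{tgt} = F({_mangle(u.state)} + dt * ({_r(u.deriv)}))")


def emit_kernel(ns_: NeuronSignature) -> KernelSource:
    """Emit the per-step kernel for one neuron type.

    Flat form unrolls every compartment; loop form emits one loop per dedup
    group with offset-shifted data slices per iteration. Both forms compute
    bit-identical trajectories.
    """
    em = _Emitter()
    em.w(0, "def kernel(V):")
    em.w(1, "F = V.F; t = V.t; dt = V.dt")

    if ns_.form == "source":
        em.w(1, f"if float(V.u_src[V.step]) < ({ns_.poisson_rate!r} * dt):")
        em.w(2, "V.spike()")
        src = em.text()
        return KernelSource(ns_.type_id, src, "kernel", _hash(src))

    em.w(1, "C = V.C; SR = V.SR; SW = V.SW; random = V.rand")

    if ns_.form == "point":
        sig = ns_.group_sigs[0]
        g = ns_.groups[0]
        _emit_member_body(
            em, 1, sig, 0, ns_,
            coff=lambda n: str(g.const_slots[n]),
            soff=lambda n: str(g.state_slots[n]),
            member_expr="0", comp_expr=None)
        # states without a derivative carry over unchanged
        updated = {u.state for u in sig.update_statements}
        all_states = [nm for nm, _, _ in sig.states]
        for st in all_states:
            if st not in updated:
                em.w(1, f"SW[{g.state_slots[st]}] = {_mangle(st)}")
        # discontinuities evaluate over the freshly written state
        for st in all_states:
            em.w(1, f"{_mangle('new_' + st)} = float(SW[{g.state_slots[st]}])")
        new_map = {st: f"new_{st}" for st in all_states}

        def ren_new(nm: str) -> str:
            return _mangle(new_map.get(nm, nm))

        for h in sig.handlers:
            if h.kind != "condition":
                continue
            em.w(1, f"if ({render_py(h.test, rename=ren_new)}) != 0.0:")
            for sv, e in h.assignments:
                em.w(2, f"{_mangle('new_' + sv)} = F({render_py(e, rename=ren_new)})")
                em.w(2, f"SW[{g.state_slots[sv]}] = {_mangle('new_' + sv)}")
            if h.emits_spike:
                em.w(2, "V.spike()")
        src = em.text()
        return KernelSource(ns_.type_id, src, "kernel", _hash(src))

    # morphological cell: flat or loop form + backward-Euler cable solve
    n = ns_.n_comps
    em.w(1, f"VV = [0.0] * {n}; CAP = [0.0] * {n}; GAX = [0.0] * {n}")
    em.w(1, f"GT = [0.0] * {n}; GE = [0.0] * {n}; II = [0.0] * {n}")
    for gi, (g, sig) in enumerate(zip(ns_.groups, ns_.group_sigs)):
        if ns_.form == "flat":
            for mi, ci in enumerate(g.members):
                em.w(1, f"# group {gi} member {mi} (compartment {ci})")
                cb = g.const_base + mi * g.const_stride
                sb = g.state_base + mi * g.state_stride
                _emit_member_body(
                    em, 1, sig, gi, ns_,
                    coff=lambda nm, cb=cb, g=g: str(cb + g.const_slots[nm]),
                    soff=lambda nm, sb=sb, g=g: str(sb + g.state_slots[nm]),
                    member_expr=str(mi), comp_expr=str(ci))
        else:
            em.w(1, f"# group {gi}: loop over {len(g.members)} members")
            em.w(1, f"_M{gi} = {tuple(g.members)!r}")
            em.w(1, f"for _j in range({len(g.members)}):")
            em.w(2, f"_cb = {g.const_base} + _j * {g.const_stride}")
            em.w(2, f"_sb = {g.state_base} + _j * {g.state_stride}")
            em.w(2, f"_ci = _M{gi}[_j]")
            _emit_member_body(
                em, 2, sig, gi, ns_,
                coff=lambda nm, g=g: f"_cb + {g.const_slots[nm]}",
                soff=lambda nm, g=g: f"_sb + {g.state_slots[nm]}",
                member_expr="_j", comp_expr="_ci")
    parent = tuple(ns_.parent)
    voff = tuple(
        ns_.groups[gi].state_base + mi * ns_.groups[gi].state_stride
        + ns_.groups[gi].state_slots["v"]
        for gi, mi in (ns_.comp_loc[ci] for ci in range(n))
    )
    em.w(1, f"PARENT = {parent!r}")
    em.w(1, f"A = [0.0] * {n}; Bc = [0.0] * {n}; R = [0.0] * {n}")
    em.w(1, f"for _i in range({n}):")
    em.w(2, "A[_i] = F(CAP[_i] / dt + GT[_i])")
    em.w(2, "R[_i] = F(CAP[_i] / dt * VV[_i] + GE[_i] + II[_i])")
    em.w(1, f"for _i in range(1, {n}):")
    em.w(2, "_p = PARENT[_i]")
    em.w(2, "if _p >= 0:")
    em.w(3, "A[_i] = F(A[_i] + GAX[_i])")
    em.w(3, "A[_p] = F(A[_p] + GAX[_i])")
    em.w(3, "Bc[_i] = -GAX[_i]")
    em.w(1, "VN = V.hines(A, Bc, R, PARENT)")
    em.w(1, f"VOFF = {voff!r}")
    em.w(1, f"for _i in range({n}):")
    em.w(2, "SW[VOFF[_i]] = F(VN[_i])")
    thr = ns_.spike_threshold
    if thr is not None:
        em.w(1, f"if F(VN[0]) >= {thr!r} and VV[0] < {thr!r}:")
        em.w(2, "V.spike()")
    src = em.text()
    return KernelSource(ns_.type_id, src, "kernel", _hash(src))


def _hash(src: str) -> str:
    return hashlib.sha256(src.encode()).hexdigest()[:16]


_KERNEL_CACHE: dict[str, Kernel] = {}


def load_kernel(ksrc: KernelSource) -> Kernel:
    """Compile and load a kernel; cached by signature hash."""
    cached = _KERNEL_CACHE.get(ksrc.provenance)
    if cached is not None:
        return cached
    env: dict = {"math": math}
    env.update(FUNCTIONS)
    try:
        code = compile(ksrc.source, f"<kernel:{ksrc.type_id}>", "exec")
        exec(code, env)
        fn = env[ksrc.entry]
    except (SyntaxError, KeyError, NameError) as exc:
        excerpt = "\n".join(ksrc.source.splitlines()[:12])
        raise GenerationBug(
            f"kernel for {ksrc.type_id!r} failed to load: {exc}\n--- source "
            f"excerpt ---\n{excerpt}"
        ) from exc
    k = Kernel(fn, ksrc.provenance, ksrc)
    _KERNEL_CACHE[ksrc.provenance] = k
    return k


def dump_kernels(sources: list[KernelSource], outdir: str) -> list[str]:
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    for ks in sources:
        path = os.path.join(outdir, f"{ks.type_id}_{ks.provenance}.py")
        with open(path, "w") as fh:
            fh.write(ks.source)
        written.append(path)
    return written
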