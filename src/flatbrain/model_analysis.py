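"""Model analysis: from the object model to per-neuron-type signatures.

The pipeline mirrors how the simulator thinks about a network:

1. :func:`discretize` splits each morphological cell into compartments and
   makes group-scoped channel densities explicit per compartment.
2. :func:`build_leaf_signature` turns each closed-form mechanism (a channel
   gate, a synapse, an input) into a code/data signature.
3. :func:`merge_signatures` composes child signatures into compartment- and
   neuron-level signatures, ordering evaluation code so every requirement is
   defined before use and concatenating the data signatures.
4. :func:`deduplicate` groups structurally identical compartments so large
   cells are simulated by a loop per compartment type instead of unrolled
   code (constants are data, not structure, so they never split a group).
5. :func:`build_work_plan` enumerates neurons into work items, one neuron per
   item, fixing the network-to-kernel mapping for the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import (
    CyclicExposureDependency,
    CyclicMorphology,
    MissingBiophysics,
    UnboundRequirement,
    UnresolvedReference,
)
from .nml_io import (
    Bin,
    Call,
    ComponentInstance,
    DynamicsSpec,
    Expr,
    Gate,
    IonChannel,
    ModelDocument,
    MorphCell,
    Network,
    Num,
    Sym,
    Un,
    eval_expr,
    expr_symbols,
    substitute,
)

#: default flattening threshold: cells with more compartments than this use
#: the per-group loop form instead of fully unrolled per-compartment code.
DEFAULT_FLATTEN_THRESHOLD = 8

DEFAULT_SPECIFIC_CAPACITANCE = 1e-2  # F/m^2 == 1 uF/cm^2


# --------------------------------------------------------------------------
# Compartments
# --------------------------------------------------------------------------


@dataclass
class Compartment:
    index: int
    seg_id: int
    parent: int  # compartment index, -1 for root
    length: float  # m
    diam_p: float
    diam_d: float
    area: float  # m^2 (frustum lateral surface; sphere for 0-length)
    capacitance: float  # F
    g_axial: float  # S, coupling to parent (0 for root)
    mechanisms: list[tuple[str, float, float]] = field(default_factory=list)
    # ^ (channel id, absolute conductance Gbar in S, erev in V), document order
    synapse_kinds: list[str] = field(default_factory=list)
    input_kinds: list[str] = field(default_factory=list)


def discretize(cell: MorphCell) -> list[Compartment]:
    """One compartment per morphological segment, topologically ordered.

    Capacitance is specific capacitance times the frustum lateral surface of
    the segment; axial conductance to the parent is (pi/4) d^2 / (Ra L) with
    the mean diameter. Group-scoped channel densities are expanded onto the
    member compartments.
    """
    seg_by_id = {s.id: s for s in cell.segments}
    children: dict[int, list[int]] = {}
    roots = []
    for s in cell.segments:
        if s.parent < 0:
            roots.append(s.id)
        else:
            if s.parent not in seg_by_id:
                raise CyclicMorphology(
                    f"cell {cell.id!r}: segment {s.id} has unknown parent {s.parent}"
                )
            children.setdefault(s.parent, []).append(s.id)
    if not roots:
        raise CyclicMorphology(f"cell {cell.id!r}: no root segment")
    order: list[int] = []
    stack = list(reversed(roots))
    seen = set()
    while stack:
        sid = stack.pop()
        if sid in seen:
            raise CyclicMorphology(f"cell {cell.id!r}: cycle at segment {sid}")
        seen.add(sid)
        order.append(sid)
        for c in reversed(children.get(sid, [])):
            stack.append(c)
    if len(order) != len(cell.segments):
        raise CyclicMorphology(f"cell {cell.id!r}: morphology is not a tree")
    if not cell.specific_capacitance and not cell.densities:
        raise MissingBiophysics(f"cell {cell.id!r} has no biophysical properties")

    idx_of = {sid: i for i, sid in enumerate(order)}
    comps: list[Compartment] = []
    for i, sid in enumerate(order):
        s = seg_by_id[sid]
        px, py, pz, pd = (u * 1e-6 for u in s.proximal)  # um -> m
        dx, dy, dz, dd = (u * 1e-6 for u in s.distal)
        length = math.sqrt((dx - px) ** 2 + (dy - py) ** 2 + (dz - pz) ** 2)
        if length == 0.0:
            area = math.pi * dd * dd  # sphere
        else:
            slant = math.sqrt(length ** 2 + ((pd - dd) / 2.0) ** 2)
            area = math.pi * ((pd + dd) / 2.0) * slant
        cm = DEFAULT_SPECIFIC_CAPACITANCE
        for group, value in cell.specific_capacitance:
            if sid in cell.groups.get(group, []):
                cm = value
        if length == 0.0:
            g_ax = 0.0 if s.parent < 0 else (
                math.pi / 4.0 * dd ** 2 / (cell.resistivity * dd)
            )
        else:
            dbar = (pd + dd) / 2.0
            g_ax = 0.0 if s.parent < 0 else (
                math.pi / 4.0 * dbar ** 2 / (cell.resistivity * length)
            )
        mechs = []
        for dens in cell.densities:
            members = cell.groups.get(dens.group)
            if members is None:
                raise UnresolvedReference(
                    f"cell {cell.id!r}: density {dens.id!r} references "
                    f"unknown group {dens.group!r}"
                )
            if sid in members:
                mechs.append((dens.channel, dens.cond_density * area, dens.erev))
        comps.append(Compartment(
            index=i, seg_id=sid,
            parent=-1 if s.parent < 0 else idx_of[s.parent],
            length=length, diam_p=pd, diam_d=dd, area=area,
            capacitance=cm * area, g_axial=g_ax, mechanisms=mechs,
        ))
    return comps


# --------------------------------------------------------------------------
# Signatures
# --------------------------------------------------------------------------


@dataclass
class Statement:
    target: str
    expr: Expr


@dataclass
class Update:
    state: str
    method: str | None  # None until the integrator is chosen; 'cable' fixed here
    deriv: Expr | None = None
    tau_sym: str | None = None  # cnexp candidates: symbols holding tau and inf
    inf_sym: str | None = None
    is_gate: bool = False


@dataclass
class Handler:
    """Cell-level discontinuity: a condition or incoming-event handler."""

    kind: str  # 'condition' | 'threshold'
    test: Expr | None  # condition: over post-update values
    assignments: list[tuple[str, Expr]] = field(default_factory=list)
    emits_spike: bool = False
    threshold: float | None = None  # 'threshold': upward crossing of v slot 0


@dataclass
class TableBlock:
    """A variable-sized population of one synapse/input kind on one group.

    Per-instance data lives in dedicated tables (one set per kind per group);
    the block's evaluation code loops over the instances attached to the
    current compartment, consumes spike flags, accumulates the current sum
    and advances per-instance state.
    """

    name: str
    kind: str  # component id of the synapse/input type
    role: str  # 'synapse' | 'gap' | 'input' | 'poisson_input'
    const_fields: list[str]
    state_fields: list[str]
    state_init: list[float]
    pre_evals: list[Statement] = field(default_factory=list)
    # ^ constant phase (parameters only), evaluated before event handling
    evals: list[Statement] = field(default_factory=list)
    # ^ state phase; may read bound requirement symbols
    updates: list[Update] = field(default_factory=list)
    on_event: list[tuple[str, Expr]] = field(default_factory=list)
    accum_sym: str = ""  # merged symbol receiving the instance-sum of 'i'
    instance_current: str = "i"
    uses_peer: bool = False
    poisson_rate: float | None = None  # per-second; per-step p = rate*dt
    requirements: dict[str, str] = field(default_factory=dict)


@dataclass
class SignatureImplementation:
    """Hierarchical record of how abstract mechanism variables map to slots."""

    paths: dict[str, dict] = field(default_factory=dict)

    def record(self, path: str, constants: dict, states: dict, integrators: dict):
        self.paths[path] = {
            "constants": constants, "states": states, "integrators": integrators,
        }


@dataclass
class Signature:
    constants: list[tuple[str, str, float]] = field(default_factory=list)
    states: list[tuple[str, str, float]] = field(default_factory=list)
    requirements: dict[str, str] = field(default_factory=dict)
    exposures: dict[str, str] = field(default_factory=dict)  # name -> symbol
    eval_statements: list[Statement] = field(default_factory=list)
    update_statements: list[Update] = field(default_factory=list)
    handlers: list[Handler] = field(default_factory=list)
    tables_needed: list[TableBlock] = field(default_factory=list)
    implementation: SignatureImplementation = field(
        default_factory=SignatureImplementation)

    def assigned_symbols(self) -> set[str]:
        return {s.target for s in self.eval_statements} | {
            tb.accum_sym for tb in self.tables_needed
        }

    def defined_symbols(self) -> set[str]:
        return (
            {n for n, _, _ in self.constants}
            | {n for n, _, _ in self.states}
            | set(self.requirements)
            | self.assigned_symbols()
            | {"t", "dt"}
        )

    def check_wellformed(self):
        """Eval-before-use: every read symbol is a constant, state,
        requirement, or previously assigned variable."""
        known = (
            {n for n, _, _ in self.constants}
            | {n for n, _, _ in self.states}
            | set(self.requirements)
            | {"t", "dt"}
        )
        for item in self.eval_statements:
            if isinstance(item, Statement):
                missing = expr_symbols(item.expr) - known
                if missing:
                    raise UnboundRequirement(
                        f"statement {item.target} reads undefined {sorted(missing)}"
                    )
                known.add(item.target)
            else:  # TableBlock: internal namespace, exposes only its sum
                for req in item.requirements:
                    if req not in known and req not in ("t", "dt"):
                        raise UnboundRequirement(
                            f"table block {item.name} requires undefined {req!r}"
                        )
                known.add(item.accum_sym)
        for u in self.update_statements:
            if u.deriv is not None:
                missing = expr_symbols(u.deriv) - known
                if missing:
                    raise UnboundRequirement(
                        f"update of {u.state} reads undefined {sorted(missing)}"
                    )
        for name, sym in self.exposures.items():
            if sym not in known:
                raise UnboundRequirement(
                    f"exposure {name} resolves to undefined symbol {sym!r}"
                )


def build_leaf_signature(dynamics: DynamicsSpec,
                         params: dict[str, float] | None = None) -> Signature:
    """Signature of a single closed-form mechanism.

    Derived variables become eval statements in DAG order, time derivatives
    become update statements (integrator not yet chosen), event/condition
    handlers are carried over. Parameters become data-signature constants
    with the instance's values as defaults; spec-level numeric constants are
    also slotted so merged signatures stay purely symbolic.
    """
    params = params or {}
    sig = Signature()
    for pname, dim in dynamics.parameters.items():
        if pname not in params:
            raise UnresolvedReference(
                f"{dynamics.name}: missing parameter value {pname!r}"
            )
        sig.constants.append((pname, dim, params[pname]))
    for cname, cval in dynamics.constants.items():
        sig.constants.append((cname, "none", cval))
    const_env = {n: v for n, _, v in sig.constants}
    init = dict(dynamics.on_start)
    for sname, dim in dynamics.state_vars.items():
        if sname in init:
            v0 = eval_expr(init[sname], const_env)
        else:
            v0 = 0.0
        sig.states.append((sname, dim, v0))
    sig.requirements = dict(dynamics.requirements)
    for n, e in dynamics.derived_vars:
        sig.eval_statements.append(Statement(n, e))
    for sv, e in dynamics.time_derivatives.items():
        sig.update_statements.append(Update(sv, None, deriv=e))
    for oc in dynamics.on_conditions:
        sig.handlers.append(Handler("condition", oc.test,
                                    list(oc.assignments),
                                    emits_spike=bool(oc.event_out)))
    for name in dynamics.exposures:
        sig.exposures[name] = name
    sig.implementation.record(
        dynamics.name,
        constants={n: n for n, _, _ in sig.constants},
        states={n: n for n, _, _ in sig.states},
        integrators={},
    )
    return sig


def _gate_rate_expr(gr, vsym: str) -> Expr:
    v = Sym(vsym)
    x = Bin("/", Bin("-", v, Num(gr.midpoint)), Num(gr.scale))
    if gr.kind == "exp":
        return Bin("*", Num(gr.rate), Call("exp", (x,)))
    if gr.kind == "sigmoid":
        return Bin("/", Num(gr.rate),
                   Bin("+", Num(1.0), Call("exp", (Un("neg", x),))))
    # explinear
    return Bin("*", Num(gr.rate), Call("explin", (x,)))


def build_channel_signature(channel: IonChannel, gbar: float, erev: float) -> Signature:
    """HH-channel signature: rate evaluations, gate states, conductance exposure.

    Gate states are flagged as cnexp candidates (alpha-beta or tau-inf
    dynamics with voltage-dependent rates); the integrator choice itself
    happens at code-generation time.
    """
    sig = Signature()
    sig.constants.append(("gbar", "conductance", gbar))
    sig.constants.append(("erev", "voltage", erev))
    sig.requirements = {"v": "voltage"}
    gate_prod: Expr = Sym("gbar")
    for g in sig_gates(channel):
        sig.states.append((g.name, "none", None))  # init: steady state at v0
        if g.mode == "rates":
            sig.eval_statements.append(
                Statement(f"{g.name}_alpha", _gate_rate_expr(g.forward, "v")))
            sig.eval_statements.append(
                Statement(f"{g.name}_beta", _gate_rate_expr(g.reverse, "v")))
            sig.eval_statements.append(Statement(
                f"{g.name}_tau",
                Bin("/", Num(1.0),
                    Bin("+", Sym(f"{g.name}_alpha"), Sym(f"{g.name}_beta")))))
            sig.eval_statements.append(Statement(
                f"{g.name}_inf",
                Bin("*", Sym(f"{g.name}_alpha"), Sym(f"{g.name}_tau"))))
        else:
            sig.eval_statements.append(
                Statement(f"{g.name}_tau", Num(g.tau)))
            sig.eval_statements.append(
                Statement(f"{g.name}_inf", _gate_rate_expr(g.steady, "v")))
        sig.update_statements.append(Update(
            g.name, None, deriv=None,
            tau_sym=f"{g.name}_tau", inf_sym=f"{g.name}_inf", is_gate=True))
        for _ in range(g.instances):
            gate_prod = Bin("*", gate_prod, Sym(g.name))
    sig.eval_statements.append(Statement("g", gate_prod))
    sig.exposures = {"g": "g", "erev": "erev"}
    sig.implementation.record(
        channel.id,
        constants={"gbar": "gbar", "erev": "erev"},
        states={g.name: g.name for g in channel.gates},
        integrators={g.name: "cnexp" for g in channel.gates},
    )
    return sig


def sig_gates(channel: IonChannel) -> list[Gate]:
    return channel.gates


def merge_signatures(parent: Signature,
                     children: list[tuple[str, Signature]],
                     bindings: dict[str, str],
                     passthrough: tuple[str, ...] = ()) -> Signature:
    """Merge child signatures into a parent signature.

    Children are namespaced by their prefix; ``bindings`` maps a (prefixed)
    requirement symbol to the merged-namespace symbol satisfying it. Any
    requirement that is neither bound nor listed in ``passthrough`` raises
    :class:`UnboundRequirement`. Evaluation code is ordered topologically so
    each mechanism's requirements are evaluated before the mechanism itself
    (ties broken by document order — parent first, then children in the
    given order); update statements are appended after all evaluations in
    the same unit order; data signatures are concatenated preserving
    per-mechanism contiguity.
    """
    units: list[tuple[str, Signature]] = [("", parent)] + list(children)

    def pref(prefix: str, name: str) -> str:
        return f"{prefix}_{name}" if prefix else name

    # per-unit renamed pieces
    renamed: list[dict] = []
    for prefix, sig in units:
        local_syms = (
            {n for n, _, _ in sig.constants}
            | {n for n, _, _ in sig.states}
            | sig.assigned_symbols()
        )
        ren = {n: pref(prefix, n) for n in local_syms}
        for req in sig.requirements:
            key = pref(prefix, req)
            if key in bindings:
                ren[req] = bindings[key]
            elif req in passthrough:
                ren[req] = req
            else:
                raise UnboundRequirement(
                    f"requirement {req!r} of unit {prefix or '<parent>'!r} "
                    f"is not bound to any exposure"
                )
        renamed.append({
            "prefix": prefix,
            "sig": sig,
            "ren": ren,
            "defines": {pref(prefix, n) for n in sig.assigned_symbols()},
        })

    # unit-level dependency graph over assigned symbols (states are read from
    # the previous step's buffer, so they never create a same-step edge)
    sym_owner: dict[str, int] = {}
    for ui, r in enumerate(renamed):
        for s in r["defines"]:
            sym_owner[s] = ui
    deps: list[set[int]] = []
    for ui, r in enumerate(renamed):
        need: set[int] = set()
        sig = r["sig"]
        reads: set[str] = set()
        for item in sig.eval_statements:
            reads |= {r["ren"].get(s, pref(r["prefix"], s))
                      for s in expr_symbols(item.expr)}
        for tb in sig.tables_needed:
            reads |= {r["ren"].get(s, s) for s in tb.requirements}
        local_defined = r["defines"] | {
            pref(r["prefix"], n) for n, _, _ in sig.constants
        } | {pref(r["prefix"], n) for n, _, _ in sig.states}
        for s in reads - local_defined:
            if s in sym_owner and sym_owner[s] != ui:
                need.add(sym_owner[s])
        deps.append(need)

    order: list[int] = []
    placed: set[int] = set()
    while len(order) < len(units):
        progress = False
        for ui in range(len(units)):
            if ui in placed:
                continue
            if deps[ui] <= placed:
                order.append(ui)
                placed.add(ui)
                progress = True
        if not progress:
            cyc = [renamed[ui]["prefix"] or "<parent>"
                   for ui in range(len(units)) if ui not in placed]
            raise CyclicExposureDependency(
                f"mechanisms form a same-step dependency cycle: {cyc}"
            )

    merged = Signature()
    # data signatures: concatenated in unit (document) order, contiguous
    for r in renamed:
        sig, prefix = r["sig"], r["prefix"]
        for n, dim, v in sig.constants:
            merged.constants.append((pref(prefix, n), dim, v))
        for n, dim, v in sig.states:
            merged.states.append((pref(prefix, n), dim, v))
        merged.implementation.record(
            prefix or "<parent>",
            constants={n: pref(prefix, n) for n, _, _ in sig.constants},
            states={n: pref(prefix, n) for n, _, _ in sig.states},
            integrators={},
        )
    # code signatures: evals in topological unit order; a unit's table
    # blocks run before its scalar statements (the accumulation statements
    # read the blocks' instance sums)
    for ui in order:
        r = renamed[ui]
        sig, ren, prefix = r["sig"], r["ren"], r["prefix"]
        full_ren = dict(ren)
        for tb in sig.tables_needed:
            merged.eval_statements.append(_rename_block(tb, prefix, full_ren))
        for item in sig.eval_statements:
            merged.eval_statements.append(Statement(
                pref(prefix, item.target),
                substitute(item.expr, full_ren)))
    # updates appended after all evals, in unit (document) order
    for r in renamed:
        sig, ren, prefix = r["sig"], r["ren"], r["prefix"]
        for u in sig.update_statements:
            merged.update_statements.append(Update(
                pref(prefix, u.state), u.method,
                deriv=substitute(u.deriv, ren) if u.deriv is not None else None,
                tau_sym=pref(prefix, u.tau_sym) if u.tau_sym else None,
                inf_sym=pref(prefix, u.inf_sym) if u.inf_sym else None,
                is_gate=u.is_gate))
        for h in sig.handlers:
            merged.handlers.append(Handler(
                h.kind,
                substitute(h.test, ren) if h.test is not None else None,
                [(ren.get(sv, pref(prefix, sv)), substitute(e, ren))
                 for sv, e in h.assignments],
                h.emits_spike, h.threshold))
    # requirements that were passed through stay requirements of the merge
    for prefix, sig in units:
        for req, dim in sig.requirements.items():
            if req in passthrough:
                merged.requirements[req] = dim
    for name, symbol in parent.exposures.items():
        merged.exposures[name] = symbol
    merged.tables_needed = [
        it for it in merged.eval_statements if isinstance(it, TableBlock)
    ]
    merged.check_wellformed()
    return merged


def _rename_block(tb: TableBlock, prefix: str, ren: dict[str, str]) -> TableBlock:
    name = f"{prefix}_{tb.name}" if prefix else tb.name
    # per-instance symbols (fields) are internal; only requirement reads and
    # the accumulator symbol live in the merged namespace
    internal = set(tb.const_fields) | set(tb.state_fields) | {
        s.target for s in tb.evals
    } | {s.target for s in tb.pre_evals}
    outer = {k: v for k, v in ren.items() if k not in internal}
    return TableBlock(
        name=name, kind=tb.kind, role=tb.role,
        const_fields=list(tb.const_fields), state_fields=list(tb.state_fields),
        state_init=list(tb.state_init),
        pre_evals=[Statement(s.target, substitute(s.expr, outer))
                   for s in tb.pre_evals],
        evals=[Statement(s.target, substitute(s.expr, outer)) for s in tb.evals],
        updates=[Update(u.state, u.method,
                        deriv=substitute(u.deriv, outer) if u.deriv else None,
                        tau_sym=u.tau_sym, inf_sym=u.inf_sym, is_gate=u.is_gate)
                 for u in tb.updates],
        on_event=[(sv, substitute(e, outer)) for sv, e in tb.on_event],
        accum_sym=ren.get(tb.accum_sym, f"{prefix}_{tb.accum_sym}" if prefix else tb.accum_sym),
        instance_current=tb.instance_current,
        uses_peer=tb.uses_peer,
        poisson_rate=tb.poisson_rate,
        requirements={outer.get(k, k): v for k, v in tb.requirements.items()},
    )


def _bind_block_syms(tb: TableBlock, mapping: dict[str, str]) -> TableBlock:
    """Rename a block's requirement symbols in place (binding to exposures)."""
    tb.evals = [Statement(s.target, substitute(s.expr, mapping))
                for s in tb.evals]
    tb.requirements = {mapping.get(k, k): v for k, v in tb.requirements.items()}
    return tb


def block_eval_phases(spec: DynamicsSpec) -> tuple[list[str], list[str]]:
    """Split a synapse/input kind's derived variables into a constant phase
    (parameters/constants only — evaluated before event handling, so event
    assignments may read them) and a state phase (evaluated after)."""
    const_known = set(spec.parameters) | set(spec.constants)
    const_names: list[str] = []
    state_names: list[str] = []
    for n, e in spec.derived_vars:
        if expr_symbols(e) <= const_known | set(const_names):
            const_names.append(n)
        else:
            state_names.append(n)
    return const_names, state_names


def make_table_block(kind_inst: ComponentInstance, name: str,
                     role: str) -> TableBlock:
    """Per-instance signature of one synapse/input kind as a table block."""
    spec = kind_inst.spec
    env = dict(kind_inst.params)
    env.update(spec.constants)
    # kind-level parameters are identical across instances: inline them
    inline = {n: Num(float(v)) for n, v in env.items()}

    def sub_params(e: Expr) -> Expr:
        return _substitute_nums(e, inline)

    const_phase, _ = block_eval_phases(spec)
    pre_evals = [Statement(n, sub_params(e)) for n, e in spec.derived_vars
                 if n in const_phase]
    evals = [Statement(n, sub_params(e)) for n, e in spec.derived_vars
             if n not in const_phase]
    updates = [Update(sv, None, deriv=sub_params(e))
               for sv, e in spec.time_derivatives.items()]
    on_event = []
    for oe in spec.on_events:
        for sv, e in oe.assignments:
            on_event.append((sv, sub_params(e)))
    init = []
    for sname in spec.state_vars:
        d = dict(spec.on_start)
        init.append(eval_expr(d[sname], env) if sname in d else 0.0)
    # weight is a per-instance constant; vpeer is satisfied per instance by
    # the stored table-offset reference to the peer's voltage slot
    reqs = {r: d for r, d in spec.requirements.items()
            if r not in ("weight", "vpeer")}
    rate = None
    if spec.poisson_rate_param:
        rate = kind_inst.params[spec.poisson_rate_param]
    return TableBlock(
        name=name, kind=kind_inst.id, role=role,
        const_fields=["weight"],
        state_fields=list(spec.state_vars),
        state_init=init,
        pre_evals=pre_evals,
        evals=evals, updates=updates, on_event=on_event,
        accum_sym=f"{name}_sum",
        uses_peer=(role == "gap"),
        poisson_rate=rate,
        requirements=reqs,
    )


def _substitute_nums(e: Expr, mapping: dict[str, Expr]) -> Expr:
    if isinstance(e, Num):
        return e
    if isinstance(e, Sym):
        return mapping.get(e.name, e)
    if isinstance(e, Un):
        return Un(e.op, _substitute_nums(e.a, mapping))
    if isinstance(e, Bin):
        return Bin(e.op, _substitute_nums(e.a, mapping),
                   _substitute_nums(e.b, mapping))
    return Call(e.fn, tuple(_substitute_nums(a, mapping) for a in e.args))


# --------------------------------------------------------------------------
# Deduplication
# --------------------------------------------------------------------------


def canonical_identity(comp: Compartment) -> tuple:
    """Structural identity of a compartment: mechanism kinds, attached
    synapse/input table kinds, and integrator structure — never constants."""
    return (
        tuple(ch for ch, _, _ in comp.mechanisms),
        tuple(comp.synapse_kinds),
        tuple(comp.input_kinds),
    )


def deduplicate(comps: list[Compartment]) -> list[list[int]]:
    """Partition compartment indices into structural-similarity groups.

    Groups are ordered by first occurrence; member lists are ascending.
    Constants (gbar, erev, capacitance, the axial conductance) are data,
    never structure, so they cannot split a group.
    """
    key_order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for c in comps:
        k = canonical_identity(c)
        if k not in groups:
            groups[k] = []
            key_order.append(k)
        groups[k].append(c.index)
    return [groups[k] for k in key_order]


# --------------------------------------------------------------------------
# Attachments
# --------------------------------------------------------------------------


def resolve_attachments(doc: ModelDocument, net: Network) -> dict[str, dict[int, tuple[list[str], list[str]]]]:
    """Per cell type: compartment index -> (synapse kinds, input kinds).

    Chemical synapses attach on the post side; gap junctions attach on both
    sides (each side tracks the peer's voltage); inputs attach on their
    target segment. Kind order is first-reference document order.
    """
    pop_by_id = {p.id: p for p in net.populations}
    seg_to_comp: dict[str, dict[int, int]] = {}
    out: dict[str, dict[int, tuple[list[str], list[str]]]] = {}

    def comp_of(type_id: str, seg: int) -> int:
        cell = doc.cells[type_id]
        if isinstance(cell, MorphCell):
            if type_id not in seg_to_comp:
                seg_to_comp[type_id] = {
                    c.seg_id: c.index for c in discretize(cell)
                }
            m = seg_to_comp[type_id]
            if seg not in m:
                raise UnresolvedReference(
                    f"segment {seg} not present on cell {type_id!r}"
                )
            return m[seg]
        return 0

    def add(type_id: str, comp: int, kind: str, which: int):
        slot = out.setdefault(type_id, {}).setdefault(comp, ([], []))
        if kind not in slot[which]:
            slot[which].append(kind)

    for p in net.populations:
        out.setdefault(p.component, {})
    for c in net.connections:
        post_type = pop_by_id[c.post_pop].component
        if c.electrical:
            pre_type = pop_by_id[c.pre_pop].component
            add(post_type, comp_of(post_type, c.post_seg), c.synapse, 0)
            add(pre_type, comp_of(pre_type, c.pre_seg), c.synapse, 0)
        else:
            add(post_type, comp_of(post_type, c.post_seg), c.synapse, 0)
    for ia in net.inputs:
        t = pop_by_id[ia.population].component
        add(t, comp_of(t, ia.segment), ia.component, 1)
    return out


# --------------------------------------------------------------------------
# Neuron-type signatures (flat and loop forms)
# --------------------------------------------------------------------------


@dataclass
class GroupLayout:
    """Data layout of one dedup group inside a neuron's flat slot arrays."""

    members: list[int]  # compartment indices
    const_base: int
    const_stride: int
    state_base: int
    state_stride: int
    const_slots: dict[str, int]  # symbol -> offset within stride
    state_slots: dict[str, int]
    const_defaults: list[list[float]]  # per member
    state_inits: list[list[float]]


@dataclass
class NeuronSignature:
    type_id: str
    cell_kind: str  # 'point' | 'morph' | 'source'
    form: str  # 'flat' | 'loop' | 'point' | 'source'
    n_comps: int
    groups: list[GroupLayout]
    group_sigs: list[Signature]
    blocks: list[list[TableBlock]]  # per group, kind order
    parent: list[int] | None = None  # morph: compartment tree
    comp_loc: list[tuple[int, int]] | None = None  # comp -> (group, member)
    spike_threshold: float | None = None  # morph threshold detection on comp 0
    poisson_rate: float | None = None  # spike sources
    v_state: str = "v"
    impl: SignatureImplementation = field(default_factory=SignatureImplementation)

    @property
    def n_const(self) -> int:
        if not self.groups:
            return 0
        g = self.groups[-1]
        return g.const_base + g.const_stride * len(g.members)

    @property
    def n_state(self) -> int:
        if not self.groups:
            return 0
        g = self.groups[-1]
        return g.state_base + g.state_stride * len(g.members)

    def state_offset(self, comp: int, symbol: str) -> int:
        gi, mi = self.comp_loc[comp]
        g = self.groups[gi]
        return g.state_base + mi * g.state_stride + g.state_slots[symbol]


def _steady_gate_init(sig: Signature, v0: float) -> dict[str, float]:
    """Gate initial values: steady state at the initial voltage."""
    env: dict[str, float] = {"v": v0, "t": 0.0, "dt": 0.0}
    for n, _, val in sig.constants:
        env[n] = val if val is not None else 0.0
    out = {}
    for item in sig.eval_statements:
        if isinstance(item, Statement):
            try:
                env[item.target] = eval_expr(item.expr, env)
            except KeyError:
                env[item.target] = 0.0
    for u in sig.update_statements:
        if u.is_gate and u.inf_sym in env:
            out[u.state] = env[u.inf_sym]
    return out


def build_compartment_signature(comp: Compartment, doc: ModelDocument,
                                attachments: tuple[list[str], list[str]],
                                multi: bool) -> Signature:
    """Merged signature of one compartment: channels + synapse/input blocks
    + the voltage aggregation/update of the compartment itself."""
    syn_kinds, inp_kinds = attachments
    children: list[tuple[str, Signature]] = []
    bindings: dict[str, str] = {}
    for i, (ch_id, gbar, erev) in enumerate(comp.mechanisms):
        ch_sig = build_channel_signature(doc.ion_channels[ch_id], gbar, erev)
        children.append((f"ch{i}", ch_sig))
        bindings[f"ch{i}_v"] = "v"

    parent = Signature()
    parent.constants.append(("cap", "capacitance", comp.capacitance))
    parent.constants.append(("gax", "conductance", comp.g_axial))
    parent.states.append(("v", "voltage", None))
    # channel-conductance aggregation (accumulation order = document order)
    stmts: list[Statement] = [Statement("gtot0", Num(0.0)), Statement("ge0", Num(0.0))]
    prev_g, prev_e = "gtot0", "ge0"
    for i in range(len(comp.mechanisms)):
        stmts.append(Statement(f"gtot{i + 1}",
                               Bin("+", Sym(prev_g), Sym(f"ch{i}_g"))))
        stmts.append(Statement(
            f"ge{i + 1}",
            Bin("+", Sym(prev_e),
                Bin("*", Sym(f"ch{i}_g"), Sym(f"ch{i}_erev")))))
        prev_g, prev_e = f"gtot{i + 1}", f"ge{i + 1}"
    stmts.append(Statement("gtot", Sym(prev_g)))
    stmts.append(Statement("ge", Sym(prev_e)))
    # synaptic/input current aggregation
    prev_i = "ii0"
    stmts.append(Statement("ii0", Num(0.0)))
    blocks: list[TableBlock] = []
    for k, kind in enumerate(list(syn_kinds) + list(inp_kinds)):
        if kind in doc.synapse_types:
            inst = doc.synapse_types[kind]
            role = "gap" if inst.spec.kind == "gap" else "synapse"
        else:
            inst = doc.input_types[kind]
            role = inst.spec.kind if inst.spec.kind in ("poisson_input",) else "input"
        tb = make_table_block(inst, f"tb{k}", role)
        blocks.append(tb)
        stmts.append(Statement(f"ii{k + 1}",
                               Bin("+", Sym(prev_i), Sym(tb.accum_sym))))
        prev_i = f"ii{k + 1}"
    stmts.append(Statement("icur", Sym(prev_i)))
    parent.eval_statements = stmts
    parent.tables_needed = blocks
    parent.exposures = {"v": "v"}
    # voltage of every morphological cell goes through the backward-Euler
    # cable path (an n=1 tree is the trivial case of the same solver)
    parent.update_statements.append(Update("v", "cable"))
    return merge_signatures(parent, children, bindings)


def build_neuron_signature(doc: ModelDocument, type_id: str,
                           attachments: dict[int, tuple[list[str], list[str]]],
                           flatten_threshold: int = DEFAULT_FLATTEN_THRESHOLD,
                           ) -> NeuronSignature:
    """Signature + data layout for one neuron type.

    Morphological cells at or under the flattening threshold use the fully
    unrolled (flat) form; larger ones use one loop per dedup group with
    offset-shifted per-iteration data slices. Both forms compute identical
    trajectories; only the generated code differs.
    """
    cell = doc.cells[type_id]
    if isinstance(cell, MorphCell):
        comps = discretize(cell)
        for c in comps:
            syn, inp = attachments.get(c.index, ([], []))
            c.synapse_kinds = list(syn)
            c.input_kinds = list(inp)
        groups_idx = deduplicate(comps)
        form = "flat" if len(comps) <= flatten_threshold else "loop"
        group_sigs: list[Signature] = []
        layouts: list[GroupLayout] = []
        blocks: list[list[TableBlock]] = []
        comp_loc: list[tuple[int, int] | None] = [None] * len(comps)
        cbase = sbase = 0
        for gi, members in enumerate(groups_idx):
            rep = comps[members[0]]
            sig = build_compartment_signature(
                rep, doc, (rep.synapse_kinds, rep.input_kinds),
                multi=len(comps) > 1)
            group_sigs.append(sig)
            blocks.append([tb for tb in sig.tables_needed])
            const_slots = {n: i for i, (n, _, _) in enumerate(sig.constants)}
            state_slots = {n: i for i, (n, _, _) in enumerate(sig.states)}
            const_defaults, state_inits = [], []
            gate_init_cache: dict[int, dict[str, float]] = {}
            for mi, ci in enumerate(members):
                comp_loc[ci] = (gi, mi)
                c = comps[ci]
                per_comp_sig = build_compartment_signature(
                    c, doc, (c.synapse_kinds, c.input_kinds),
                    multi=len(comps) > 1)
                const_defaults.append([v if v is not None else 0.0
                                       for _, _, v in per_comp_sig.constants])
                ginit = _steady_gate_init(per_comp_sig, cell.init_v)
                inits = []
                for n, _, v in per_comp_sig.states:
                    if n == "v":
                        inits.append(cell.init_v)
                    elif n in ginit:
                        inits.append(ginit[n])
                    else:
                        inits.append(v if v is not None else 0.0)
                state_inits.append(inits)
            layouts.append(GroupLayout(
                members=list(members),
                const_base=cbase, const_stride=len(sig.constants),
                state_base=sbase, state_stride=len(sig.states),
                const_slots=const_slots, state_slots=state_slots,
                const_defaults=const_defaults, state_inits=state_inits,
            ))
            cbase += len(sig.constants) * len(members)
            sbase += len(sig.states) * len(members)
        return NeuronSignature(
            type_id=type_id, cell_kind="morph", form=form,
            n_comps=len(comps), groups=layouts, group_sigs=group_sigs,
            blocks=blocks, parent=[c.parent for c in comps],
            comp_loc=comp_loc, spike_threshold=cell.spike_thresh,
        )

    inst: ComponentInstance = cell
    if inst.spec.kind == "spike_source":
        return NeuronSignature(
            type_id=type_id, cell_kind="source", form="source", n_comps=0,
            groups=[], group_sigs=[], blocks=[],
            poisson_rate=inst.params[inst.spec.poisson_rate_param],
        )
    # point cell: cell dynamics + attached kinds feeding iSyn
    syn, inp = attachments.get(0, ([], []))
    leaf = build_leaf_signature(inst.spec, inst.params)
    parent = Signature()
    parent.constants = []
    parent.states = []
    stmts = [Statement("isyn0", Num(0.0))]
    blocks_here: list[TableBlock] = []
    prev = "isyn0"
    for k, kind in enumerate(list(syn) + list(inp)):
        if kind in doc.synapse_types:
            ki = doc.synapse_types[kind]
            role = "gap" if ki.spec.kind == "gap" else "synapse"
        else:
            ki = doc.input_types[kind]
            role = ki.spec.kind if ki.spec.kind == "poisson_input" else "input"
        tb = make_table_block(ki, f"tb{k}", role)
        blocks_here.append(tb)
        stmts.append(Statement(f"isyn{k + 1}",
                               Bin("+", Sym(prev), Sym(tb.accum_sym))))
        prev = f"isyn{k + 1}"
    stmts.append(Statement("isyn_total", Sym(prev)))
    # blocks read the cell's voltage state from the previous-step buffer
    if "v" in inst.spec.state_vars:
        for tb in blocks_here:
            _bind_block_syms(tb, {"v": "cell_v"})
    parent.eval_statements = stmts
    parent.tables_needed = blocks_here
    bindings = {}
    if "iSyn" in inst.spec.requirements:
        bindings["cell_iSyn"] = "isyn_total"
    merged = merge_signatures(parent, [("cell", leaf)], bindings)
    blocks_here = merged.tables_needed  # the merged (renamed) block objects
    for name, sym in leaf.exposures.items():
        merged.exposures[name] = f"cell_{sym}"
    const_slots = {n: i for i, (n, _, _) in enumerate(merged.constants)}
    state_slots = {n: i for i, (n, _, _) in enumerate(merged.states)}
    layout = GroupLayout(
        members=[0], const_base=0, const_stride=len(merged.constants),
        state_base=0, state_stride=len(merged.states),
        const_slots=const_slots, state_slots=state_slots,
        const_defaults=[[v if v is not None else 0.0
                         for _, _, v in merged.constants]],
        state_inits=[[v if v is not None else 0.0
                      for _, _, v in merged.states]],
    )
    return NeuronSignature(
        type_id=type_id, cell_kind="point", form="point", n_comps=1,
        groups=[layout], group_sigs=[merged], blocks=[blocks_here],
        parent=[-1], comp_loc=[(0, 0)], v_state="cell_v",
    )


# --------------------------------------------------------------------------
# Work plan
# --------------------------------------------------------------------------


@dataclass
class WorkItem:
    index: int  # global neuron index, gapless 0-based
    type_id: str
    population: str
    instance: int


@dataclass
class WorkPlan:
    types: dict[str, NeuronSignature]
    items: list[WorkItem]
    pop_offset: dict[str, int]

    def neuron_index(self, pop: str, inst: int) -> int:
        return self.pop_offset[pop] + inst

    @property
    def n_neurons(self) -> int:
        return len(self.items)


def build_work_plan(doc: ModelDocument, net: Network | None = None,
                    flatten_threshold: int = DEFAULT_FLATTEN_THRESHOLD) -> WorkPlan:
    """Enumerate neurons population-by-population into work items and build
    one signature per neuron type."""
    if net is None:
        net = doc.network()
    attachments = resolve_attachments(doc, net)
    types: dict[str, NeuronSignature] = {}
    for p in net.populations:
        if p.component not in types:
            types[p.component] = build_neuron_signature(
                doc, p.component, attachments.get(p.component, {}),
                flatten_threshold)
    items: list[WorkItem] = []
    pop_offset: dict[str, int] = {}
    idx = 0
    for p in net.populations:
        pop_offset[p.id] = idx
        for i in range(p.size):
            items.append(WorkItem(idx, p.component, p.id, i))
            idx += 1
    return WorkPlan(types, items, pop_offset)


def dump_analysis(plan: WorkPlan) -> str:
    """Plain-text report of per-type groups, signature sizes and slot maps."""
    lines = []
    for tid, ns in plan.types.items():
        lines.append(f"type {tid}: kind={ns.cell_kind} form={ns.form} "
                     f"comps={ns.n_comps} groups={len(ns.groups)} "
                     f"consts={ns.n_const} states={ns.n_state}")
        for gi, g in enumerate(ns.groups):
            lines.append(f"  group {gi}: members={len(g.members)} "
                         f"const_stride={g.const_stride} "
                         f"state_stride={g.state_stride}")
            lines.append(f"    states: {sorted(g.state_slots, key=g.state_slots.get)}")
    n_by_type: dict[str, int] = {}
    for it in plan.items:
        n_by_type[it.type_id] = n_by_type.get(it.type_id, 0) + 1
    lines.append(f"work items: {len(plan.items)} "
                 + " ".join(f"{k}:{v}" for k, v in n_by_type.items()))
    return "\n".join(lines) + "\n"
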