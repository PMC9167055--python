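"""Reading and writing the supported NeuroML-v2 / LEMS subset.

The reader produces a fully-resolved :class:`ModelDocument`; the writer emits
documents that parse back to an equal object model, which is the round-trip
contract the fixture generators rely on. Output trajectories are written in
jLEMS-compatible whitespace-separated columns (time in seconds, values in SI).

Supported component types: ``izhikevichCell``, ``izhikevich2007Cell``,
``iafCell``, ``iafTauCell``, ``adExIaFCell``, morphological ``cell`` with
HH-style channel densities, ``expOneSynapse``, ``expTwoSynapse``,
``gapJunction``, ``pulseGenerator``, ``spikeGeneratorPoisson``,
``poissonFiringSynapse``, populations, chemical/electrical projections and
input lists, plus custom LEMS ``ComponentType`` point neurons. Anything else
raises :class:`~flatbrain.errors.UnsupportedElement`.
"""

from __future__ import annotations

import logging
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .errors import (
    CyclicDerivedVariables,
    DimensionMismatch,
    MissingSimulation,
    UnknownFunction,
    UnknownUnit,
    UnresolvedProbePath,
    UnresolvedReference,
    UnsupportedElement,
    UnsupportedLemsFeature,
)
from .runtime import FUNCTIONS

log = logging.getLogger("flatbrain.nml_io")

# --------------------------------------------------------------------------
# Units
# --------------------------------------------------------------------------

#: unit symbol -> (factor to SI, dimension name). Closed table: unknown units
#: are always an error, never silently treated as SI.
UNIT_TABLE: dict[str, tuple[float, str]] = {
    # voltage
    "V": (1.0, "voltage"),
    "mV": (1e-3, "voltage"),
    "uV": (1e-6, "voltage"),
    # time
    "s": (1.0, "time"),
    "ms": (1e-3, "time"),
    "us": (1e-6, "time"),
    # rate
    "per_s": (1.0, "per_time"),
    "per_ms": (1e3, "per_time"),
    "Hz": (1.0, "per_time"),
    # current
    "A": (1.0, "current"),
    "mA": (1e-3, "current"),
    "uA": (1e-6, "current"),
    "nA": (1e-9, "current"),
    "pA": (1e-12, "current"),
    # conductance
    "S": (1.0, "conductance"),
    "mS": (1e-3, "conductance"),
    "uS": (1e-6, "conductance"),
    "nS": (1e-9, "conductance"),
    "pS": (1e-12, "conductance"),
    # capacitance
    "F": (1.0, "capacitance"),
    "uF": (1e-6, "capacitance"),
    "nF": (1e-9, "capacitance"),
    "pF": (1e-12, "capacitance"),
    # resistance
    "ohm": (1.0, "resistance"),
    "kohm": (1e3, "resistance"),
    "Mohm": (1e6, "resistance"),
    # length
    "m": (1.0, "length"),
    "cm": (1e-2, "length"),
    "um": (1e-6, "length"),
    # conductance density
    "S_per_m2": (1.0, "conductance_density"),
    "mS_per_cm2": (10.0, "conductance_density"),
    "S_per_cm2": (1e4, "conductance_density"),
    "uS_per_cm2": (1e-2, "conductance_density"),
    # specific capacitance
    "F_per_m2": (1.0, "specific_capacitance"),
    "uF_per_cm2": (1e-2, "specific_capacitance"),
    # resistivity
    "ohm_m": (1.0, "resistivity"),
    "ohm_cm": (1e-2, "resistivity"),
    "kohm_cm": (10.0, "resistivity"),
    # conductance per voltage (Izhikevich-2007 k)
    "S_per_V": (1.0, "conductance_per_voltage"),
    "nS_per_mV": (1e-6, "conductance_per_voltage"),
}

#: SI unit symbol used when re-serializing each dimension.
SI_UNIT = {
    "voltage": "V",
    "time": "s",
    "per_time": "per_s",
    "current": "A",
    "conductance": "S",
    "capacitance": "F",
    "resistance": "ohm",
    "length": "m",
    "conductance_density": "S_per_m2",
    "specific_capacitance": "F_per_m2",
    "resistivity": "ohm_m",
    "conductance_per_voltage": "S_per_V",
    "none": "",
}


@dataclass(frozen=True)
class Quantity:
    """A dimensional value stored in SI."""

    magnitude: float
    dimension: str

    def __str__(self) -> str:
        unit = SI_UNIT.get(self.dimension, "")
        return f"{self.magnitude!r} {unit}".strip()


_QTY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*([A-Za-z_][A-Za-z0-9_]*)?\s*$"
)


def parse_quantity(text: str) -> Quantity:
    m = _QTY_RE.match(text)
    if not m:
        raise UnknownUnit(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2)
    if unit is None:
        return Quantity(value, "none")
    if unit not in UNIT_TABLE:
        raise UnknownUnit(f"unknown unit {unit!r} in {text!r}")
    factor, dim = UNIT_TABLE[unit]
    return Quantity(value * factor, dim)


def to_si(text: str, expect: str | None = None) -> float:
    """Convert ``"<number><unit>"`` to its SI magnitude.

    When ``expect`` is given the quantity's dimension must match.
    """
    q = parse_quantity(text)
    if expect is not None and expect != "none" and q.dimension not in (expect, "none"):
        raise DimensionMismatch(
            f"{text!r} has dimension {q.dimension}, expected {expect}"
        )
    return q.magnitude


# --------------------------------------------------------------------------
# LEMS expression language
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Num:
    v: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class Bin:
    op: str  # + - * / ^ gt lt geq leq eq neq and or
    a: "Expr"
    b: "Expr"


@dataclass(frozen=True)
class Un:
    op: str  # neg
    a: "Expr"


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple


Expr = Num | Sym | Bin | Un | Call

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<word>\.?(?:gt|lt|geq|leq|eq|neq|and|or)\.|[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|!=|[-+*/^()<>,])"
    r")"
)

_WORD_OPS = {
    ".gt.": "gt", ">": "gt",
    ".lt.": "lt", "<": "lt",
    ".geq.": "geq", ">=": "geq",
    ".leq.": "leq", "<=": "leq",
    ".eq.": "eq", "==": "eq",
    ".neq.": "neq", "!=": "neq",
    ".and.": "and",
    ".or.": "or",
}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise UnknownFunction(f"cannot tokenize expression at {text[pos:]!r}")
        pos = m.end()
        if m.group("num"):
            tokens.append(("num", m.group("num")))
        elif m.group("word"):
            w = m.group("word")
            if w in _WORD_OPS:
                tokens.append(("cmp", _WORD_OPS[w]))
            else:
                tokens.append(("name", w))
        else:
            op = m.group("op")
            tokens.append(("cmp", _WORD_OPS[op]) if op in _WORD_OPS else ("op", op))
    tokens.append(("end", ""))
    return tokens


class _Parser:
    """Recursive-descent parser: or < and < comparison < add < mul < unary < pow."""

    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def take(self):
        t = self.toks[self.i]
        self.i += 1
        return t

    def expect_op(self, op):
        kind, val = self.take()
        if kind != "op" or val != op:
            raise UnknownFunction(f"expected {op!r} in {self.text!r}, got {val!r}")

    def parse(self) -> Expr:
        e = self.p_or()
        if self.peek()[0] != "end":
            raise UnknownFunction(f"trailing tokens in {self.text!r}")
        return e

    def p_or(self):
        e = self.p_and()
        while self.peek() == ("cmp", "or"):
            self.take()
            e = Bin("or", e, self.p_and())
        return e

    def p_and(self):
        e = self.p_cmp()
        while self.peek() == ("cmp", "and"):
            self.take()
            e = Bin("and", e, self.p_cmp())
        return e

    def p_cmp(self):
        e = self.p_add()
        kind, val = self.peek()
        if kind == "cmp" and val not in ("and", "or"):
            self.take()
            return Bin(val, e, self.p_add())
        return e

    def p_add(self):
        e = self.p_mul()
        while self.peek()[0] == "op" and self.peek()[1] in "+-":
            _, op = self.take()
            e = Bin(op, e, self.p_mul())
        return e

    def p_mul(self):
        e = self.p_unary()
        while self.peek()[0] == "op" and self.peek()[1] in "*/":
            _, op = self.take()
            e = Bin(op, e, self.p_unary())
        return e

    def p_unary(self):
        kind, val = self.peek()
        if kind == "op" and val == "-":
            self.take()
            return Un("neg", self.p_unary())
        if kind == "op" and val == "+":
            self.take()
            return self.p_unary()
        return self.p_pow()

    def p_pow(self):
        e = self.p_atom()
        if self.peek() == ("op", "^"):
            self.take()
            return Bin("^", e, self.p_unary())  # right-associative
        return e

    def p_atom(self):
        kind, val = self.take()
        if kind == "num":
            return Num(float(val))
        if kind == "name":
            if self.peek() == ("op", "("):
                self.take()
                args = []
                if self.peek() != ("op", ")"):
                    args.append(self.p_or())
                    while self.peek() == ("op", ","):
                        self.take()
                        args.append(self.p_or())
                self.expect_op(")")
                if val not in FUNCTIONS and val != "random":
                    raise UnknownFunction(f"unknown function {val!r}")
                return Call(val, tuple(args))
            return Sym(val)
        if kind == "op" and val == "(":
            e = self.p_or()
            self.expect_op(")")
            return e
        raise UnknownFunction(f"unexpected token {val!r} in {self.text!r}")


def parse_expr(text: str) -> Expr:
    return _Parser(text).parse()


def expr_symbols(e: Expr) -> set[str]:
    if isinstance(e, Num):
        return set()
    if isinstance(e, Sym):
        return {e.name}
    if isinstance(e, Un):
        return expr_symbols(e.a)
    if isinstance(e, Bin):
        return expr_symbols(e.a) | expr_symbols(e.b)
    out = set()
    for a in e.args:
        out |= expr_symbols(a)
    return out


def substitute(e: Expr, mapping: dict[str, str]) -> Expr:
    """Rename symbols (used when binding child requirements to exposures)."""
    if isinstance(e, Num):
        return e
    if isinstance(e, Sym):
        return Sym(mapping.get(e.name, e.name))
    if isinstance(e, Un):
        return Un(e.op, substitute(e.a, mapping))
    if isinstance(e, Bin):
        return Bin(e.op, substitute(e.a, mapping), substitute(e.b, mapping))
    return Call(e.fn, tuple(substitute(a, mapping) for a in e.args))


_CMP_PY = {"gt": ">", "lt": "<", "geq": ">=", "leq": "<=", "eq": "==", "neq": "!="}
_CMP_LEMS = {v: k for k, v in _CMP_PY.items()}


def eval_expr(e: Expr, env, funcs=FUNCTIONS) -> float:
    """Interpret an expression over an environment of python floats.

    Comparisons and logic evaluate to 1.0/0.0 so predicates and arithmetic
    share one semantics; the code generator renders the same semantics.
    """
    if isinstance(e, Num):
        return e.v
    if isinstance(e, Sym):
        return env[e.name]
    if isinstance(e, Un):
        return -eval_expr(e.a, env, funcs)
    if isinstance(e, Bin):
        a = eval_expr(e.a, env, funcs)
        b = eval_expr(e.b, env, funcs)
        op = e.op
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        if op == "^":
            return a ** b
        if op == "and":
            return 1.0 if (a != 0.0 and b != 0.0) else 0.0
        if op == "or":
            return 1.0 if (a != 0.0 or b != 0.0) else 0.0
        if op == "gt":
            return 1.0 if a > b else 0.0
        if op == "lt":
            return 1.0 if a < b else 0.0
        if op == "geq":
            return 1.0 if a >= b else 0.0
        if op == "leq":
            return 1.0 if a <= b else 0.0
        if op == "eq":
            return 1.0 if a == b else 0.0
        if op == "neq":
            return 1.0 if a != b else 0.0
        raise UnknownFunction(f"operator {op!r}")
    return funcs[e.fn](*(eval_expr(a, env, funcs) for a in e.args))


def render_py(e: Expr, rename=None) -> str:
    """Render an expression as python source with identical evaluation order."""
    r = (lambda x: render_py(x, rename))
    if isinstance(e, Num):
        return repr(e.v)
    if isinstance(e, Sym):
        return rename(e.name) if rename else e.name
    if isinstance(e, Un):
        return f"(-{r(e.a)})"
    if isinstance(e, Bin):
        if e.op in "+-*/":
            return f"({r(e.a)} {e.op} {r(e.b)})"
        if e.op == "^":
            return f"({r(e.a)} ** {r(e.b)})"
        if e.op == "and":
            return f"(1.0 if (({r(e.a)}) != 0.0 and ({r(e.b)}) != 0.0) else 0.0)"
        if e.op == "or":
            return f"(1.0 if (({r(e.a)}) != 0.0 or ({r(e.b)}) != 0.0) else 0.0)"
        return f"(1.0 if ({r(e.a)} {_CMP_PY[e.op]} {r(e.b)}) else 0.0)"
    args = ", ".join(r(a) for a in e.args)
    return f"{e.fn}({args})"


def render_lems(e: Expr) -> str:
    """Render an expression back to LEMS syntax (fully parenthesized)."""
    if isinstance(e, Num):
        return repr(e.v)
    if isinstance(e, Sym):
        return e.name
    if isinstance(e, Un):
        return f"(-{render_lems(e.a)})"
    if isinstance(e, Bin):
        if e.op in "+-*/^":
            return f"({render_lems(e.a)} {e.op} {render_lems(e.b)})"
        return f"({render_lems(e.a)} .{e.op}. {render_lems(e.b)})"
    args = ", ".join(render_lems(a) for a in e.args)
    return f"{e.fn}({args})"


# --------------------------------------------------------------------------
# Dynamics specifications
# --------------------------------------------------------------------------


@dataclass
class OnCondition:
    test: Expr
    assignments: list[tuple[str, Expr]]
    event_out: list[str]


@dataclass
class OnEvent:
    port: str
    assignments: list[tuple[str, Expr]]


@dataclass
class DynamicsSpec:
    """Dynamics of one mechanism: states, derived variables, handlers.

    ``derived_vars`` is stored in dependency (DAG) order after validation.
    ``kind`` classifies how the instantiator wires the mechanism up:
    ``cell`` / ``synapse`` / ``gap`` / ``input`` / ``poisson_input`` /
    ``spike_source``.
    """

    name: str
    parameters: dict[str, str] = field(default_factory=dict)  # name -> dimension
    constants: dict[str, float] = field(default_factory=dict)
    requirements: dict[str, str] = field(default_factory=dict)
    exposures: dict[str, str] = field(default_factory=dict)
    state_vars: dict[str, str] = field(default_factory=dict)
    derived_vars: list[tuple[str, Expr]] = field(default_factory=list)
    time_derivatives: dict[str, Expr] = field(default_factory=dict)
    on_start: list[tuple[str, Expr]] = field(default_factory=list)
    on_conditions: list[OnCondition] = field(default_factory=list)
    on_events: list[OnEvent] = field(default_factory=list)
    event_ports_in: list[str] = field(default_factory=list)
    event_ports_out: list[str] = field(default_factory=list)
    kind: str = "cell"
    poisson_rate_param: str | None = None  # set for self-firing components

    def validate(self) -> "DynamicsSpec":
        declared = (
            set(self.parameters)
            | set(self.constants)
            | set(self.requirements)
            | set(self.state_vars)
            | {"t", "dt"}
        )
        # order derived variables as a DAG (Kahn; ties keep declaration order)
        names = [n for n, _ in self.derived_vars]
        exprs = dict(self.derived_vars)
        deps = {
            n: expr_symbols(e) & set(names) for n, e in self.derived_vars
        }
        ordered: list[str] = []
        placed: set[str] = set()
        while len(ordered) < len(names):
            progress = False
            for n in names:
                if n in placed:
                    continue
                if deps[n] <= placed:
                    ordered.append(n)
                    placed.add(n)
                    progress = True
            if not progress:
                cyc = [n for n in names if n not in placed]
                raise CyclicDerivedVariables(
                    f"{self.name}: cyclic derived variables {cyc}"
                )
        self.derived_vars = [(n, exprs[n]) for n in ordered]
        all_known = declared | set(names)
        for n, e in self.derived_vars:
            missing = expr_symbols(e) - all_known
            if missing:
                raise UnresolvedReference(
                    f"{self.name}: derived variable {n} references {sorted(missing)}"
                )
        for sv, e in self.time_derivatives.items():
            if sv not in self.state_vars:
                raise UnresolvedReference(
                    f"{self.name}: derivative of undeclared state {sv}"
                )
            missing = expr_symbols(e) - all_known
            if missing:
                raise UnresolvedReference(
                    f"{self.name}: d{sv}/dt references {sorted(missing)}"
                )
        for exp_name in self.exposures:
            if exp_name not in self.state_vars and exp_name not in placed \
                    and exp_name not in self.parameters:
                raise UnresolvedReference(
                    f"{self.name}: exposure {exp_name} resolves to nothing"
                )
        return self


# --------------------------------------------------------------------------
# Built-in component library
# --------------------------------------------------------------------------

_E = parse_expr


def _izhikevich_cell() -> DynamicsSpec:
    # Classic dimensionless Izhikevich model; v kept in volts, the canonical
    # mV/ms form falls out because mV/ms == V/s numerically.
    return DynamicsSpec(
        name="izhikevichCell",
        parameters={"v0": "voltage", "a": "none", "b": "none", "c": "none",
                    "d": "none", "thresh": "voltage"},
        constants={"MV": 1000.0},
        state_vars={"v": "voltage", "u": "none"},
        derived_vars=[("vm", _E("v*MV"))],
        time_derivatives={
            "v": _E("0.04*vm^2 + 5*vm + 140 - u"),
            "u": _E("MV*a*(b*vm - u)"),
        },
        on_start=[("v", _E("v0")), ("u", _E("b*v0*MV"))],
        on_conditions=[OnCondition(_E("v .geq. thresh"),
                                   [("v", _E("c/MV")), ("u", _E("u + d"))],
                                   ["spike"])],
        event_ports_out=["spike"],
        exposures={"v": "voltage", "u": "none"},
        kind="cell",
    ).validate()


def _izhikevich2007_cell() -> DynamicsSpec:
    return DynamicsSpec(
        name="izhikevich2007Cell",
        parameters={"v0": "voltage", "k": "conductance_per_voltage",
                    "vr": "voltage", "vt": "voltage", "vpeak": "voltage",
                    "a": "per_time", "b": "conductance", "c": "voltage",
                    "d": "current", "C": "capacitance"},
        state_vars={"v": "voltage", "u": "current"},
        requirements={"iSyn": "current"},
        time_derivatives={
            "v": _E("(k*(v-vr)*(v-vt) - u + iSyn)/C"),
            "u": _E("a*(b*(v-vr) - u)"),
        },
        on_start=[("v", _E("v0")), ("u", _E("0"))],
        on_conditions=[OnCondition(_E("v .geq. vpeak"),
                                   [("v", _E("c")), ("u", _E("u + d"))],
                                   ["spike"])],
        event_ports_out=["spike"],
        exposures={"v": "voltage", "u": "current"},
        kind="cell",
    ).validate()


def _iaf_cell() -> DynamicsSpec:
    return DynamicsSpec(
        name="iafCell",
        parameters={"leakReversal": "voltage", "thresh": "voltage",
                    "reset": "voltage", "C": "capacitance",
                    "leakConductance": "conductance"},
        state_vars={"v": "voltage"},
        requirements={"iSyn": "current"},
        time_derivatives={"v": _E("(leakConductance*(leakReversal - v) + iSyn)/C")},
        on_start=[("v", _E("reset"))],
        on_conditions=[OnCondition(_E("v .geq. thresh"),
                                   [("v", _E("reset"))], ["spike"])],
        event_ports_out=["spike"],
        exposures={"v": "voltage"},
        kind="cell",
    ).validate()


def _iaf_tau_cell() -> DynamicsSpec:
    return DynamicsSpec(
        name="iafTauCell",
        parameters={"leakReversal": "voltage", "thresh": "voltage",
                    "reset": "voltage", "tau": "time"},
        state_vars={"v": "voltage"},
        time_derivatives={"v": _E("(leakReversal - v)/tau")},
        on_start=[("v", _E("reset"))],
        on_conditions=[OnCondition(_E("v .geq. thresh"),
                                   [("v", _E("reset"))], ["spike"])],
        event_ports_out=["spike"],
        exposures={"v": "voltage"},
        kind="cell",
    ).validate()


def _adex_cell() -> DynamicsSpec:
    return DynamicsSpec(
        name="adExIaFCell",
        parameters={"C": "capacitance", "gL": "conductance", "EL": "voltage",
                    "VT": "voltage", "thresh": "voltage", "delT": "voltage",
                    "tauw": "time", "a": "conductance", "b": "current",
                    "reset": "voltage"},
        state_vars={"v": "voltage", "w": "current"},
        requirements={"iSyn": "current"},
        time_derivatives={
            "v": _E("(gL*(EL - v) + gL*delT*exp((v - VT)/delT) - w + iSyn)/C"),
            "w": _E("(a*(v - EL) - w)/tauw"),
        },
        on_start=[("v", _E("EL")), ("w", _E("0"))],
        on_conditions=[OnCondition(_E("v .geq. thresh"),
                                   [("v", _E("reset")), ("w", _E("w + b"))],
                                   ["spike"])],
        event_ports_out=["spike"],
        exposures={"v": "voltage", "w": "current"},
        kind="cell",
    ).validate()


def _exp_one_synapse() -> DynamicsSpec:
    return DynamicsSpec(
        name="expOneSynapse",
        parameters={"gbase": "conductance", "erev": "voltage",
                    "tauDecay": "time"},
        state_vars={"g": "conductance"},
        requirements={"v": "voltage", "weight": "none"},
        derived_vars=[("i", _E("g*(erev - v)"))],
        time_derivatives={"g": _E("-g/tauDecay")},
        on_start=[("g", _E("0"))],
        on_events=[OnEvent("in", [("g", _E("g + gbase*weight"))])],
        event_ports_in=["in"],
        exposures={"i": "current", "g": "conductance"},
        kind="synapse",
    ).validate()


def _exp_two_synapse() -> DynamicsSpec:
    # peakTime/waveformFactor normalize the double exponential so the peak
    # conductance of a unit-weight event is gbase.
    return DynamicsSpec(
        name="expTwoSynapse",
        parameters={"gbase": "conductance", "erev": "voltage",
                    "tauRise": "time", "tauDecay": "time"},
        state_vars={"A": "none", "B": "none"},
        requirements={"v": "voltage", "weight": "none"},
        derived_vars=[
            ("peakTime", _E("ln(tauDecay/tauRise)*(tauRise*tauDecay)/(tauDecay - tauRise)")),
            ("waveformFactor", _E("1/((-exp(-peakTime/tauRise)) + exp(-peakTime/tauDecay))")),
            ("g", _E("gbase*(B - A)")),
            ("i", _E("g*(erev - v)")),
        ],
        time_derivatives={"A": _E("-A/tauRise"), "B": _E("-B/tauDecay")},
        on_start=[("A", _E("0")), ("B", _E("0"))],
        on_events=[OnEvent("in", [("A", _E("A + weight*waveformFactor")),
                                  ("B", _E("B + weight*waveformFactor"))])],
        event_ports_in=["in"],
        exposures={"i": "current", "g": "conductance"},
        kind="synapse",
    ).validate()


def _gap_junction() -> DynamicsSpec:
    return DynamicsSpec(
        name="gapJunction",
        parameters={"conductance": "conductance"},
        requirements={"v": "voltage", "vpeer": "voltage", "weight": "none"},
        derived_vars=[("i", _E("weight*conductance*(vpeer - v)"))],
        exposures={"i": "current"},
        kind="gap",
    ).validate()


def _pulse_generator() -> DynamicsSpec:
    return DynamicsSpec(
        name="pulseGenerator",
        parameters={"delay": "time", "duration": "time", "amplitude": "current"},
        requirements={"weight": "none"},
        derived_vars=[("i", _E("weight*amplitude*((t .geq. delay) * (t .lt. (delay + duration)))"))],
        exposures={"i": "current"},
        kind="input",
    ).validate()


def _spike_generator_poisson() -> DynamicsSpec:
    return DynamicsSpec(
        name="spikeGeneratorPoisson",
        parameters={"averageRate": "per_time"},
        event_ports_out=["spike"],
        exposures={},
        kind="spike_source",
        poisson_rate_param="averageRate",
    ).validate()


def _poisson_firing_synapse() -> DynamicsSpec:
    # Self-firing conductance input: an exponential synapse whose presynaptic
    # drive is a Poisson stream of the given rate.
    return DynamicsSpec(
        name="poissonFiringSynapse",
        parameters={"averageRate": "per_time", "gbase": "conductance",
                    "erev": "voltage", "tauDecay": "time"},
        state_vars={"g": "conductance"},
        requirements={"v": "voltage", "weight": "none"},
        derived_vars=[("i", _E("g*(erev - v)"))],
        time_derivatives={"g": _E("-g/tauDecay")},
        on_start=[("g", _E("0"))],
        on_events=[OnEvent("in", [("g", _E("g + gbase*weight"))])],
        event_ports_in=["in"],
        event_ports_out=["spike"],
        exposures={"i": "current"},
        kind="poisson_input",
        poisson_rate_param="averageRate",
    ).validate()


BUILTIN_TYPES: dict[str, DynamicsSpec] = {}


def _builtin(name: str) -> DynamicsSpec:
    if not BUILTIN_TYPES:
        for f in (_izhikevich_cell, _izhikevich2007_cell, _iaf_cell,
                  _iaf_tau_cell, _adex_cell, _exp_one_synapse,
                  _exp_two_synapse, _gap_junction, _pulse_generator,
                  _spike_generator_poisson, _poisson_firing_synapse):
            s = f()
            BUILTIN_TYPES[s.name] = s
    return BUILTIN_TYPES[name]


for _name in ("izhikevichCell",):
    _builtin(_name)  # populate on import


# --------------------------------------------------------------------------
# Object model
# --------------------------------------------------------------------------


@dataclass
class ComponentInstance:
    """A concrete mechanism: a dynamics spec plus SI parameter values."""

    id: str
    type_name: str
    spec: DynamicsSpec
    params: dict[str, float]


@dataclass
class Segment:
    id: int
    name: str
    parent: int  # -1 for root
    proximal: tuple[float, float, float, float]  # x,y,z,diameter (um)
    distal: tuple[float, float, float, float]


@dataclass
class GateRate:
    kind: str  # 'exp' | 'sigmoid' | 'explinear'
    rate: float  # per_s
    midpoint: float  # V
    scale: float  # V


@dataclass
class Gate:
    name: str
    instances: int
    mode: str  # 'rates' | 'tauinf'
    forward: GateRate | None = None
    reverse: GateRate | None = None
    tau: float | None = None  # fixed time course (s), tauinf mode
    steady: GateRate | None = None  # sigmoid-style steady state, tauinf mode


@dataclass
class IonChannel:
    id: str
    gates: list[Gate]  # empty -> passive


@dataclass
class ChannelDensity:
    id: str
    channel: str
    cond_density: float  # S/m^2
    erev: float  # V
    group: str  # segment group ('all' default)


@dataclass
class MorphCell:
    id: str
    segments: list[Segment]
    groups: dict[str, list[int]]
    densities: list[ChannelDensity]
    specific_capacitance: list[tuple[str, float]]  # (group, F/m^2)
    resistivity: float  # ohm m
    init_v: float  # V
    spike_thresh: float  # V


@dataclass
class Population:
    id: str
    component: str
    size: int


@dataclass
class Connection:
    synapse: str
    pre_pop: str
    pre_inst: int
    pre_seg: int
    pre_frac: float
    post_pop: str
    post_inst: int
    post_seg: int
    post_frac: float
    weight: float = 1.0
    delay: float = 0.0  # seconds
    electrical: bool = False


@dataclass
class InputAttachment:
    component: str
    population: str
    instance: int
    segment: int
    fraction: float
    weight: float = 1.0


@dataclass
class Network:
    id: str
    populations: list[Population]
    connections: list[Connection]  # document order, chemical + electrical
    inputs: list[InputAttachment]


@dataclass
class ModelDocument:
    component_types: dict[str, DynamicsSpec] = field(default_factory=dict)
    cells: dict[str, object] = field(default_factory=dict)  # MorphCell | ComponentInstance
    ion_channels: dict[str, IonChannel] = field(default_factory=dict)
    synapse_types: dict[str, ComponentInstance] = field(default_factory=dict)
    input_types: dict[str, ComponentInstance] = field(default_factory=dict)
    networks: dict[str, Network] = field(default_factory=dict)

    def network(self, name: str | None = None) -> Network:
        if name is None:
            if len(self.networks) != 1:
                raise UnresolvedReference(
                    f"expected one network, have {sorted(self.networks)}"
                )
            return next(iter(self.networks.values()))
        if name not in self.networks:
            raise UnresolvedReference(f"network {name!r} not defined")
        return self.networks[name]


@dataclass
class OutputFileSpec:
    path: str
    columns: list[str]  # symbolic probe paths


@dataclass
class EventFileSpec:
    path: str
    selections: list[str]  # symbolic cell paths
    port: str = "spike"
    format: str = "ID_TIME"


@dataclass
class SimulationSpec:
    target: str  # network id
    duration: float  # s
    dt: float  # s
    seed: int = 12345
    output_files: list[OutputFileSpec] = field(default_factory=list)
    event_files: list[EventFileSpec] = field(default_factory=list)

    @property
    def steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class ProbeTarget:
    population: str
    instance: int
    segment: int
    variable: str


# --------------------------------------------------------------------------
# XML parsing
# --------------------------------------------------------------------------

_IGNORED_TAGS = {"notes", "annotation", "property", "Meta", "meta"}

_SUPPORTED_CELL_TAGS = {
    "izhikevichCell", "izhikevich2007Cell", "iafCell", "iafTauCell",
    "adExIaFCell",
}
_SUPPORTED_SYNAPSE_TAGS = {"expOneSynapse", "expTwoSynapse", "gapJunction"}
_SUPPORTED_INPUT_TAGS = {"pulseGenerator", "spikeGeneratorPoisson",
                         "poissonFiringSynapse"}


def _local(tag) -> str:
    if isinstance(tag, str):
        return tag.rsplit("}", 1)[-1]
    return ""  # comments / PIs


def _attr_si(el, name: str, expect: str | None = None, default=None):
    raw = el.get(name)
    if raw is None:
        if default is not None:
            return default
        raise UnresolvedReference(
            f"<{_local(el.tag)} id={el.get('id')!r}> missing attribute {name!r}"
        )
    return to_si(raw, expect)


def _instance_from_element(el, spec: DynamicsSpec) -> ComponentInstance:
    params = {}
    for pname, dim in spec.parameters.items():
        raw = el.get(pname)
        if raw is None:
            raise UnresolvedReference(
                f"<{_local(el.tag)} id={el.get('id')!r}> missing parameter {pname!r}"
            )
        params[pname] = to_si(raw, dim)
    return ComponentInstance(el.get("id"), spec.name, spec, params)


def _parse_gate_rate(el) -> GateRate:
    kind_map = {
        "HHExpRate": "exp",
        "HHSigmoidRate": "sigmoid",
        "HHExpLinearRate": "explinear",
        "HHSigmoidVariable": "sigmoid",
        "HHExpVariable": "exp",
        "HHExpLinearVariable": "explinear",
    }
    t = el.get("type")
    if t not in kind_map:
        raise UnsupportedElement(f"unsupported rate type {t!r}")
    return GateRate(
        kind=kind_map[t],
        rate=to_si(el.get("rate")),
        midpoint=to_si(el.get("midpoint"), "voltage"),
        scale=to_si(el.get("scale"), "voltage"),
    )


def _parse_ion_channel(el) -> IonChannel:
    gates = []
    for child in el:
        tag = _local(child.tag)
        if tag in _IGNORED_TAGS or tag == "":
            continue
        if tag == "gateHHrates":
            fwd = rev = None
            for sub in child:
                st = _local(sub.tag)
                if st == "forwardRate":
                    fwd = _parse_gate_rate(sub)
                elif st == "reverseRate":
                    rev = _parse_gate_rate(sub)
                elif st in _IGNORED_TAGS or st == "":
                    continue
                else:
                    raise UnsupportedElement(f"<{st}> inside gateHHrates")
            if fwd is None or rev is None:
                raise UnresolvedReference(
                    f"gate {child.get('id')!r} needs forwardRate and reverseRate"
                )
            gates.append(Gate(child.get("id"), int(child.get("instances", "1")),
                              "rates", forward=fwd, reverse=rev))
        elif tag == "gateHHtauInf":
            tau = steady = None
            for sub in child:
                st = _local(sub.tag)
                if st == "timeCourse":
                    if sub.get("type") != "fixedTimeCourse":
                        raise UnsupportedElement(
                            f"timeCourse type {sub.get('type')!r}"
                        )
                    tau = to_si(sub.get("tau"), "time")
                elif st == "steadyState":
                    steady = _parse_gate_rate(sub)
                elif st in _IGNORED_TAGS or st == "":
                    continue
                else:
                    raise UnsupportedElement(f"<{st}> inside gateHHtauInf")
            if tau is None or steady is None:
                raise UnresolvedReference(
                    f"gate {child.get('id')!r} needs timeCourse and steadyState"
                )
            gates.append(Gate(child.get("id"), int(child.get("instances", "1")),
                              "tauinf", tau=tau, steady=steady))
        else:
            raise UnsupportedElement(f"<{tag}> inside ionChannel")
    return IonChannel(el.get("id"), gates)


def _parse_morph_cell(el) -> MorphCell:
    segments: list[Segment] = []
    groups: dict[str, list[int]] = {}
    densities: list[ChannelDensity] = []
    spec_cap: list[tuple[str, float]] = []
    resistivity = 1.0
    init_v = -0.065
    spike_thresh = -0.020
    seg_by_id: dict[int, Segment] = {}
    for section in el:
        tag = _local(section.tag)
        if tag in _IGNORED_TAGS or tag == "":
            continue
        if tag == "morphology":
            for child in section:
                ctag = _local(child.tag)
                if ctag == "segment":
                    sid = int(child.get("id"))
                    parent = -1
                    prox = dist = None
                    for sub in child:
                        st = _local(sub.tag)
                        if st == "parent":
                            parent = int(sub.get("segment"))
                        elif st == "proximal":
                            prox = tuple(
                                float(sub.get(a)) for a in "xyz"
                            ) + (float(sub.get("diameter")),)
                        elif st == "distal":
                            dist = tuple(
                                float(sub.get(a)) for a in "xyz"
                            ) + (float(sub.get("diameter")),)
                    if dist is None:
                        raise UnresolvedReference(
                            f"segment {sid} of cell {el.get('id')!r} has no distal point"
                        )
                    if prox is None:
                        if parent not in seg_by_id:
                            raise UnresolvedReference(
                                f"segment {sid}: no proximal point and no parent"
                            )
                        prox = seg_by_id[parent].distal
                    seg = Segment(sid, child.get("name", f"seg{sid}"),
                                  parent, prox, dist)
                    segments.append(seg)
                    seg_by_id[sid] = seg
                elif ctag == "segmentGroup":
                    members: list[int] = []
                    for sub in child:
                        st = _local(sub.tag)
                        if st == "member":
                            members.append(int(sub.get("segment")))
                        elif st == "include":
                            members.extend(groups.get(sub.get("segmentGroup"), []))
                        elif st in _IGNORED_TAGS or st == "":
                            continue
                        else:
                            raise UnsupportedElement(f"<{st}> inside segmentGroup")
                    groups[child.get("id")] = members
                elif ctag in _IGNORED_TAGS or ctag == "":
                    continue
                else:
                    raise UnsupportedElement(f"<{ctag}> inside morphology")
        elif tag == "biophysicalProperties":
            for part in section:
                ptag = _local(part.tag)
                if ptag == "membraneProperties":
                    for sub in part:
                        st = _local(sub.tag)
                        if st == "channelDensity":
                            densities.append(ChannelDensity(
                                id=sub.get("id"),
                                channel=sub.get("ionChannel"),
                                cond_density=to_si(sub.get("condDensity"),
                                                   "conductance_density"),
                                erev=to_si(sub.get("erev"), "voltage"),
                                group=sub.get("segmentGroup", "all"),
                            ))
                        elif st == "specificCapacitance":
                            spec_cap.append((sub.get("segmentGroup", "all"),
                                             to_si(sub.get("value"),
                                                   "specific_capacitance")))
                        elif st == "initMembPotential":
                            init_v = to_si(sub.get("value"), "voltage")
                        elif st == "spikeThresh":
                            spike_thresh = to_si(sub.get("value"), "voltage")
                        elif st in _IGNORED_TAGS or st == "":
                            continue
                        else:
                            raise UnsupportedElement(
                                f"<{st}> inside membraneProperties"
                            )
                elif ptag == "intracellularProperties":
                    for sub in part:
                        st = _local(sub.tag)
                        if st == "resistivity":
                            resistivity = to_si(sub.get("value"), "resistivity")
                        elif st in _IGNORED_TAGS or st == "":
                            continue
                        else:
                            raise UnsupportedElement(
                                f"<{st}> inside intracellularProperties"
                            )
                elif ptag in _IGNORED_TAGS or ptag == "":
                    continue
                else:
                    raise UnsupportedElement(f"<{ptag}> inside biophysicalProperties")
        else:
            raise UnsupportedElement(f"<{tag}> inside cell")
    groups.setdefault("all", [s.id for s in segments])
    return MorphCell(el.get("id"), segments, groups, densities, spec_cap,
                     resistivity, init_v, spike_thresh)


_CELL_REF_RE = re.compile(r"(?:\.\./)?([A-Za-z_][\w]*)[/\[](\d+)\]?")


def _parse_cell_ref(text: str) -> tuple[str, int]:
    """Extract (population, instance) from refs like '../pop/3/type' or 'pop[3]'."""
    m = _CELL_REF_RE.match(text.strip())
    if not m:
        raise UnresolvedReference(f"cannot parse cell reference {text!r}")
    return m.group(1), int(m.group(2))


def _parse_network(el) -> Network:
    pops: list[Population] = []
    conns: list[Connection] = []
    inputs: list[InputAttachment] = []
    for child in el:
        tag = _local(child.tag)
        if tag in _IGNORED_TAGS or tag == "":
            continue
        if tag == "population":
            instances = [sub for sub in child if _local(sub.tag) == "instance"]
            size = int(child.get("size", len(instances) or 0))
            if size < 1:
                raise UnresolvedReference(
                    f"population {child.get('id')!r} has size {size}"
                )
            pops.append(Population(child.get("id"), child.get("component"), size))
        elif tag == "projection":
            syn = child.get("synapse")
            pre_pop_default = child.get("presynapticPopulation")
            post_pop_default = child.get("postsynapticPopulation")
            for sub in child:
                st = _local(sub.tag)
                if st not in ("connection", "connectionWD"):
                    if st in _IGNORED_TAGS or st == "":
                        continue
                    raise UnsupportedElement(f"<{st}> inside projection")
                pre_pop, pre_inst = _parse_cell_ref(sub.get("preCellId"))
                post_pop, post_inst = _parse_cell_ref(sub.get("postCellId"))
                if pre_pop_default and pre_pop != pre_pop_default:
                    pre_pop = pre_pop_default
                if post_pop_default and post_pop != post_pop_default:
                    post_pop = post_pop_default
                conns.append(Connection(
                    synapse=syn,
                    pre_pop=pre_pop, pre_inst=pre_inst,
                    pre_seg=int(sub.get("preSegmentId", "0")),
                    pre_frac=float(sub.get("preFractionAlong", "0.5")),
                    post_pop=post_pop, post_inst=post_inst,
                    post_seg=int(sub.get("postSegmentId", "0")),
                    post_frac=float(sub.get("postFractionAlong", "0.5")),
                    weight=float(sub.get("weight", "1")),
                    delay=to_si(sub.get("delay", "0ms"), "time"),
                ))
        elif tag == "electricalProjection":
            pre_pop = child.get("presynapticPopulation")
            post_pop = child.get("postsynapticPopulation")
            for sub in child:
                st = _local(sub.tag)
                if st not in ("electricalConnection",
                              "electricalConnectionInstance",
                              "electricalConnectionInstanceW"):
                    if st in _IGNORED_TAGS or st == "":
                        continue
                    raise UnsupportedElement(f"<{st}> inside electricalProjection")
                pre_ref = sub.get("preCell")
                post_ref = sub.get("postCell")
                if "/" in pre_ref or "[" in pre_ref:
                    _, pre_inst = _parse_cell_ref(pre_ref)
                else:
                    pre_inst = int(pre_ref)
                if "/" in post_ref or "[" in post_ref:
                    _, post_inst = _parse_cell_ref(post_ref)
                else:
                    post_inst = int(post_ref)
                conns.append(Connection(
                    synapse=sub.get("synapse"),
                    pre_pop=pre_pop, pre_inst=pre_inst,
                    pre_seg=int(sub.get("preSegment", "0")),
                    pre_frac=float(sub.get("preFractionAlong", "0.5")),
                    post_pop=post_pop, post_inst=post_inst,
                    post_seg=int(sub.get("postSegment", "0")),
                    post_frac=float(sub.get("postFractionAlong", "0.5")),
                    weight=float(sub.get("weight", "1")),
                    electrical=True,
                ))
        elif tag == "inputList":
            comp = child.get("component")
            pop = child.get("population")
            for sub in child:
                st = _local(sub.tag)
                if st not in ("input", "inputW"):
                    if st in _IGNORED_TAGS or st == "":
                        continue
                    raise UnsupportedElement(f"<{st}> inside inputList")
                _, inst = _parse_cell_ref(sub.get("target"))
                inputs.append(InputAttachment(
                    component=comp, population=pop, instance=inst,
                    segment=int(sub.get("segmentId", "0")),
                    fraction=float(sub.get("fractionAlong", "0.5")),
                    weight=float(sub.get("weight", "1")),
                ))
        elif tag == "explicitInput":
            inputs.append(InputAttachment(
                component=child.get("input"),
                population=_parse_cell_ref(child.get("target"))[0],
                instance=_parse_cell_ref(child.get("target"))[1],
                segment=0, fraction=0.5,
            ))
        else:
            raise UnsupportedElement(f"<{tag}> inside network")
    return Network(el.get("id"), pops, conns, inputs)


def parse_dynamics(el) -> DynamicsSpec:
    """Parse a LEMS ``<ComponentType>`` with a Dynamics block."""
    spec = DynamicsSpec(name=el.get("name"))
    extends = el.get("extends", "")
    if "Synapse" in extends or "synapse" in extends:
        spec.kind = "synapse"
    elif "PointCurrent" in extends or "Input" in extends:
        spec.kind = "input"
    else:
        spec.kind = "cell"
    for child in el:
        tag = _local(child.tag)
        if tag in _IGNORED_TAGS or tag == "":
            continue
        if tag == "Parameter":
            spec.parameters[child.get("name")] = child.get("dimension", "none")
        elif tag == "Constant":
            spec.constants[child.get("name")] = to_si(child.get("value"))
        elif tag == "Requirement":
            spec.requirements[child.get("name")] = child.get("dimension", "none")
        elif tag == "Exposure":
            spec.exposures[child.get("name")] = child.get("dimension", "none")
        elif tag == "EventPort":
            if child.get("direction") == "in":
                spec.event_ports_in.append(child.get("name"))
            else:
                spec.event_ports_out.append(child.get("name"))
        elif tag == "Dynamics":
            for d in child:
                dtag = _local(d.tag)
                if dtag in ("KineticScheme", "Regime"):
                    raise UnsupportedLemsFeature(f"LEMS {dtag} is not supported")
                if dtag == "StateVariable":
                    spec.state_vars[d.get("name")] = d.get("dimension", "none")
                elif dtag == "DerivedVariable":
                    if d.get("value") is None:
                        raise UnsupportedLemsFeature(
                            "DerivedVariable without value (select/reduce)"
                        )
                    spec.derived_vars.append(
                        (d.get("name"), parse_expr(d.get("value")))
                    )
                elif dtag == "TimeDerivative":
                    spec.time_derivatives[d.get("variable")] = \
                        parse_expr(d.get("value"))
                elif dtag == "OnStart":
                    for a in d:
                        if _local(a.tag) == "StateAssignment":
                            spec.on_start.append(
                                (a.get("variable"), parse_expr(a.get("value")))
                            )
                elif dtag == "OnCondition":
                    assigns, events = [], []
                    for a in d:
                        atag = _local(a.tag)
                        if atag == "StateAssignment":
                            assigns.append(
                                (a.get("variable"), parse_expr(a.get("value")))
                            )
                        elif atag == "EventOut":
                            events.append(a.get("port"))
                    spec.on_conditions.append(
                        OnCondition(parse_expr(d.get("test")), assigns, events)
                    )
                elif dtag == "OnEvent":
                    assigns = []
                    for a in d:
                        if _local(a.tag) == "StateAssignment":
                            assigns.append(
                                (a.get("variable"), parse_expr(a.get("value")))
                            )
                    spec.on_events.append(OnEvent(d.get("port"), assigns))
                elif dtag in _IGNORED_TAGS or dtag == "":
                    continue
                else:
                    raise UnsupportedLemsFeature(f"Dynamics child <{dtag}>")
        else:
            raise UnsupportedLemsFeature(f"ComponentType child <{tag}>")
    return spec.validate()


@dataclass
class _ParseState:
    doc: ModelDocument
    simulations: list  # raw <Simulation> elements (with base dir)
    seen_files: set


def _parse_file_into(path: str, st: _ParseState, stack: tuple = ()):
    real = os.path.realpath(path)
    if real in stack:
        raise UnresolvedReference(f"cyclic <Include> chain at {path}")
    if real in st.seen_files:
        return
    st.seen_files.add(real)
    tree = etree.parse(path)
    root = tree.getroot()
    if _local(root.tag) not in ("neuroml", "Lems"):
        raise UnsupportedElement(f"unsupported document root <{_local(root.tag)}>")
    base = os.path.dirname(real)
    for el in root:
        tag = _local(el.tag)
        if tag in _IGNORED_TAGS or tag == "":
            continue
        if tag in ("include", "Include"):
            href = el.get("href") or el.get("file")
            _parse_file_into(os.path.join(base, href), st, stack + (real,))
        elif tag == "Target":
            continue
        elif tag == "ComponentType":
            spec = parse_dynamics(el)
            st.doc.component_types[spec.name] = spec
        elif tag == "Simulation":
            st.simulations.append(el)
        elif tag in _SUPPORTED_CELL_TAGS:
            inst = _instance_from_element(el, _builtin(tag))
            st.doc.cells[inst.id] = inst
        elif tag in _SUPPORTED_SYNAPSE_TAGS:
            inst = _instance_from_element(el, _builtin(tag))
            st.doc.synapse_types[inst.id] = inst
        elif tag in _SUPPORTED_INPUT_TAGS:
            inst = _instance_from_element(el, _builtin(tag))
            st.doc.input_types[inst.id] = inst
            if tag == "spikeGeneratorPoisson":
                # usable both as an input component and as a population's
                # (spike-source) cell type
                st.doc.cells[inst.id] = inst
        elif tag in ("ionChannel", "ionChannelHH", "ionChannelPassive"):
            ch = _parse_ion_channel(el)
            st.doc.ion_channels[ch.id] = ch
        elif tag == "cell":
            cell = _parse_morph_cell(el)
            st.doc.cells[cell.id] = cell
        elif tag == "network":
            net = _parse_network(el)
            st.doc.networks[net.id] = net
        elif tag in st.doc.component_types:
            # instance of a previously declared custom ComponentType
            spec = st.doc.component_types[tag]
            inst = _instance_from_element(el, spec)
            if spec.kind == "synapse":
                st.doc.synapse_types[inst.id] = inst
            elif spec.kind == "input":
                st.doc.input_types[inst.id] = inst
            else:
                st.doc.cells[inst.id] = inst
        else:
            raise UnsupportedElement(f"unsupported element <{tag}>")


def _validate_document(doc: ModelDocument):
    for net in doc.networks.values():
        pop_by_id = {p.id: p for p in net.populations}
        for p in net.populations:
            if p.component not in doc.cells:
                raise UnresolvedReference(
                    f"population {p.id!r} references undefined cell {p.component!r}"
                )
        for c in net.connections:
            if c.synapse not in doc.synapse_types:
                raise UnresolvedReference(
                    f"connection references undefined synapse {c.synapse!r}"
                )
            for pop, inst in ((c.pre_pop, c.pre_inst), (c.post_pop, c.post_inst)):
                if pop not in pop_by_id:
                    raise UnresolvedReference(
                        f"connection references undefined population {pop!r}"
                    )
                if not (0 <= inst < pop_by_id[pop].size):
                    raise UnresolvedReference(
                        f"connection endpoint {pop}[{inst}] out of range"
                    )
        for ia in net.inputs:
            if ia.component not in doc.input_types:
                raise UnresolvedReference(
                    f"input list references undefined input {ia.component!r}"
                )
            if ia.population not in pop_by_id:
                raise UnresolvedReference(
                    f"input list references undefined population {ia.population!r}"
                )
            if not (0 <= ia.instance < pop_by_id[ia.population].size):
                raise UnresolvedReference(
                    f"input target {ia.population}[{ia.instance}] out of range"
                )


def parse_model(paths: list[str] | str) -> ModelDocument:
    """Read one or more NeuroML/LEMS files into a resolved ModelDocument."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    st = _ParseState(ModelDocument(), [], set())
    for p in paths:
        _parse_file_into(os.fspath(p), st)
    _validate_document(st.doc)
    return st.doc


def parse_model_string(xml: str, extra: dict[str, str] | None = None) -> ModelDocument:
    """Parse in-memory XML (used by the fixture generators and tests)."""
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        main = os.path.join(d, "main.xml")
        with open(main, "w") as fh:
            fh.write(xml)
        for name, content in (extra or {}).items():
            with open(os.path.join(d, name), "w") as fh:
                fh.write(content)
        return parse_model(main)


def resolve_probe(doc: ModelDocument, net: Network, path: str) -> ProbeTarget:
    """Resolve a symbolic probe path like ``pop[3]/v`` or ``pop/3/celltype/0/v``."""
    tokens = [t for t in re.split(r"[/\[\]]+", path.strip()) if t]
    if len(tokens) < 2:
        raise UnresolvedProbePath(f"malformed probe path {path!r}")
    pop_by_id = {p.id: p for p in net.populations}
    if tokens[0] not in pop_by_id:
        raise UnresolvedProbePath(f"{path!r}: unknown population {tokens[0]!r}")
    pop = pop_by_id[tokens[0]]
    try:
        inst = int(tokens[1])
    except ValueError:
        raise UnresolvedProbePath(f"{path!r}: expected instance index")
    if not (0 <= inst < pop.size):
        raise UnresolvedProbePath(f"{path!r}: instance {inst} out of range")
    rest = tokens[2:]
    # optional cell-type token
    if rest and rest[0] == pop.component:
        rest = rest[1:]
    seg = 0
    if len(rest) == 2:
        try:
            seg = int(rest[0])
        except ValueError:
            raise UnresolvedProbePath(f"{path!r}: bad segment id {rest[0]!r}")
        rest = rest[1:]
    if len(rest) != 1:
        raise UnresolvedProbePath(f"{path!r}: cannot resolve variable")
    var = rest[0]
    cell = doc.cells[pop.component]
    if isinstance(cell, MorphCell):
        if seg not in {s.id for s in cell.segments}:
            raise UnresolvedProbePath(f"{path!r}: segment {seg} not in cell")
        if var != "v":
            raise UnresolvedProbePath(
                f"{path!r}: only 'v' is recordable on morphological cells"
            )
    else:
        if seg != 0:
            raise UnresolvedProbePath(f"{path!r}: point cell has no segment {seg}")
        ok = set(cell.spec.state_vars) | set(cell.spec.exposures)
        if var not in ok:
            raise UnresolvedProbePath(f"{path!r}: unknown variable {var!r}")
    return ProbeTarget(pop.id, inst, seg, var)


def load_simulation(path: str) -> tuple[ModelDocument, SimulationSpec]:
    """Load a LEMS file containing a ``<Simulation>`` plus the model it includes."""
    st = _ParseState(ModelDocument(), [], set())
    _parse_file_into(os.fspath(path), st)
    _validate_document(st.doc)
    if not st.simulations:
        raise MissingSimulation(f"no <Simulation> element found in {path}")
    el = st.simulations[0]
    spec = SimulationSpec(
        target=el.get("target"),
        duration=to_si(el.get("length"), "time"),
        dt=to_si(el.get("step"), "time"),
        seed=int(el.get("seed", "12345")),
    )
    if spec.dt <= 0 or spec.duration < spec.dt:
        raise MissingSimulation(
            f"invalid timing: length={spec.duration}, step={spec.dt}"
        )
    net = st.doc.network(spec.target)
    for child in el:
        tag = _local(child.tag)
        if tag == "OutputFile":
            cols = [sub.get("quantity") for sub in child
                    if _local(sub.tag) == "OutputColumn"]
            for c in cols:
                resolve_probe(st.doc, net, c)
            spec.output_files.append(OutputFileSpec(child.get("fileName"), cols))
        elif tag == "EventOutputFile":
            sels, port = [], "spike"
            for sub in child:
                if _local(sub.tag) == "EventSelection":
                    sels.append(sub.get("select"))
                    port = sub.get("eventPort", "spike")
            for s in sels:
                pop, inst = _parse_cell_ref(s)
                pops = {p.id: p for p in net.populations}
                if pop not in pops or not (0 <= inst < pops[pop].size):
                    raise UnresolvedProbePath(f"event selection {s!r} unresolved")
            spec.event_files.append(EventFileSpec(
                child.get("fileName"), sels, port,
                child.get("format", "ID_TIME")))
        elif tag in _IGNORED_TAGS or tag == "":
            continue
    return st.doc, spec


# --------------------------------------------------------------------------
# Recording output (jLEMS-style flat text)
# --------------------------------------------------------------------------


def write_recordings(recording, spec: SimulationSpec, outdir: str = ".") -> list[str]:
    """Write waveform ``.dat`` and event files for a finished simulation.

    Waveform files: whitespace-separated columns, first column time (s), one
    row per recorded step, all values SI, ``%.17g`` so doubles round-trip
    exactly. Event files: one ``index<TAB>time`` row per spike, sorted by
    time (``TIME_ID`` format swaps the columns). Output is bit-identical for
    identical recordings.
    """
    written = []
    col_index = {p: i for i, p in enumerate(recording.probe_paths)}
    for of in spec.output_files:
        path = os.path.join(outdir, of.path)
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        with open(path, "w") as fh:
            for r in range(len(recording.times)):
                row = [f"{recording.times[r]:.17g}"]
                for c in of.columns:
                    row.append(f"{recording.waveforms[col_index[c]][r]:.17g}")
                fh.write("\t".join(row) + "\n")
        written.append(path)
    for ef in spec.event_files:
        sel_index = {}
        for i, s in enumerate(ef.selections):
            sel_index[_parse_cell_ref(s)] = i
        rows = []
        for neuron, t_spike in recording.spikes:
            key = recording.neuron_labels[neuron]
            if key in sel_index:
                rows.append((t_spike, sel_index[key]))
        rows.sort()
        path = os.path.join(outdir, ef.path)
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        with open(path, "w") as fh:
            for t_spike, idx in rows:
                if ef.format == "TIME_ID":
                    fh.write(f"{t_spike:.17g}\t{idx}\n")
                else:
                    fh.write(f"{idx}\t{t_spike:.17g}\n")
        written.append(path)
    return written


def read_waveforms(path: str) -> np.ndarray:
    """Read a waveform ``.dat`` file back as an array (rows x columns)."""
    data = np.loadtxt(path, ndmin=2)
    return data


def read_events(path: str, format: str = "ID_TIME") -> list[tuple[int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if format == "TIME_ID":
                out.append((int(parts[1]), float(parts[0])))
            else:
                out.append((int(parts[0]), float(parts[1])))
    return out


# --------------------------------------------------------------------------
# Serialization (subset writer; parse(serialize(doc)) == doc)
# --------------------------------------------------------------------------


def _fmt(value: float, dim: str) -> str:
    unit = SI_UNIT.get(dim, "")
    return f"{value!r}{unit}"


def _serialize_component(inst: ComponentInstance) -> str:
    attrs = [f'id="{inst.id}"']
    for pname, dim in inst.spec.parameters.items():
        attrs.append(f'{pname}="{_fmt(inst.params[pname], dim)}"')
    return f"  <{inst.type_name} {' '.join(attrs)}/>"


def _serialize_dynamics(spec: DynamicsSpec) -> str:
    out = [f'  <ComponentType name="{spec.name}" extends="baseCell">']
    for n, d in spec.parameters.items():
        out.append(f'    <Parameter name="{n}" dimension="{d}"/>')
    for n, v in spec.constants.items():
        out.append(f'    <Constant name="{n}" dimension="none" value="{v!r}"/>')
    for n, d in spec.requirements.items():
        out.append(f'    <Requirement name="{n}" dimension="{d}"/>')
    for n, d in spec.exposures.items():
        out.append(f'    <Exposure name="{n}" dimension="{d}"/>')
    for p in spec.event_ports_in:
        out.append(f'    <EventPort name="{p}" direction="in"/>')
    for p in spec.event_ports_out:
        out.append(f'    <EventPort name="{p}" direction="out"/>')
    out.append("    <Dynamics>")
    for n, d in spec.state_vars.items():
        out.append(f'      <StateVariable name="{n}" dimension="{d}"/>')
    for n, e in spec.derived_vars:
        out.append(f'      <DerivedVariable name="{n}" value="{render_lems(e)}"/>')
    for sv, e in spec.time_derivatives.items():
        out.append(f'      <TimeDerivative variable="{sv}" value="{render_lems(e)}"/>')
    if spec.on_start:
        out.append("      <OnStart>")
        for sv, e in spec.on_start:
            out.append(f'        <StateAssignment variable="{sv}" value="{render_lems(e)}"/>')
        out.append("      </OnStart>")
    for oc in spec.on_conditions:
        out.append(f'      <OnCondition test="{render_lems(oc.test)}">')
        for sv, e in oc.assignments:
            out.append(f'        <StateAssignment variable="{sv}" value="{render_lems(e)}"/>')
        for p in oc.event_out:
            out.append(f'        <EventOut port="{p}"/>')
        out.append("      </OnCondition>")
    for oe in spec.on_events:
        out.append(f'      <OnEvent port="{oe.port}">')
        for sv, e in oe.assignments:
            out.append(f'        <StateAssignment variable="{sv}" value="{render_lems(e)}"/>')
        out.append("      </OnEvent>")
    out.append("    </Dynamics>")
    out.append("  </ComponentType>")
    return "\n".join(out)


def _um(x: float) -> str:
    return repr(x)  # morphology coordinates are stored in micrometers


def _serialize_morph_cell(cell: MorphCell) -> str:
    out = [f'  <cell id="{cell.id}">', '    <morphology id="morph">']
    for s in cell.segments:
        out.append(f'      <segment id="{s.id}" name="{s.name}">')
        if s.parent >= 0:
            out.append(f'        <parent segment="{s.parent}"/>')
        px, py, pz, pd = s.proximal
        dx, dy, dz, dd = s.distal
        out.append(f'        <proximal x="{_um(px)}" y="{_um(py)}" z="{_um(pz)}" diameter="{_um(pd)}"/>')
        out.append(f'        <distal x="{_um(dx)}" y="{_um(dy)}" z="{_um(dz)}" diameter="{_um(dd)}"/>')
        out.append("      </segment>")
    for gname, members in cell.groups.items():
        out.append(f'      <segmentGroup id="{gname}">')
        for m in members:
            out.append(f'        <member segment="{m}"/>')
        out.append("      </segmentGroup>")
    out.append("    </morphology>")
    out.append('    <biophysicalProperties id="biophys">')
    out.append("      <membraneProperties>")
    for d in cell.densities:
        out.append(
            f'        <channelDensity id="{d.id}" ionChannel="{d.channel}" '
            f'condDensity="{_fmt(d.cond_density, "conductance_density")}" '
            f'erev="{_fmt(d.erev, "voltage")}" segmentGroup="{d.group}"/>'
        )
    out.append(f'        <spikeThresh value="{_fmt(cell.spike_thresh, "voltage")}"/>')
    for g, v in cell.specific_capacitance:
        out.append(f'        <specificCapacitance value="{_fmt(v, "specific_capacitance")}" segmentGroup="{g}"/>')
    out.append(f'        <initMembPotential value="{_fmt(cell.init_v, "voltage")}"/>')
    out.append("      </membraneProperties>")
    out.append("      <intracellularProperties>")
    out.append(f'        <resistivity value="{_fmt(cell.resistivity, "resistivity")}"/>')
    out.append("      </intracellularProperties>")
    out.append("    </biophysicalProperties>")
    out.append("  </cell>")
    return "\n".join(out)


def _serialize_rate(tag: str, r: GateRate) -> str:
    type_map = {"exp": "HHExpRate", "sigmoid": "HHSigmoidRate",
                "explinear": "HHExpLinearRate"}
    return (f'        <{tag} type="{type_map[r.kind]}" rate="{r.rate!r}per_s" '
            f'midpoint="{_fmt(r.midpoint, "voltage")}" scale="{_fmt(r.scale, "voltage")}"/>')


def _serialize_channel(ch: IonChannel) -> str:
    out = [f'  <ionChannelHH id="{ch.id}">']
    for g in ch.gates:
        if g.mode == "rates":
            out.append(f'      <gateHHrates id="{g.name}" instances="{g.instances}">')
            out.append(_serialize_rate("forwardRate", g.forward))
            out.append(_serialize_rate("reverseRate", g.reverse))
            out.append("      </gateHHrates>")
        else:
            out.append(f'      <gateHHtauInf id="{g.name}" instances="{g.instances}">')
            out.append(f'        <timeCourse type="fixedTimeCourse" tau="{_fmt(g.tau, "time")}"/>')
            out.append(_serialize_rate("steadyState", g.steady))
            out.append("      </gateHHtauInf>")
    out.append("  </ionChannelHH>")
    return "\n".join(out)


def serialize_model(doc: ModelDocument) -> str:
    """Serialize a ModelDocument back to a single NeuroML/LEMS document."""
    out = ['<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="doc">']
    for spec in doc.component_types.values():
        out.append(_serialize_dynamics(spec))
    for ch in doc.ion_channels.values():
        out.append(_serialize_channel(ch))
    for cell in doc.cells.values():
        if isinstance(cell, MorphCell):
            out.append(_serialize_morph_cell(cell))
        elif cell.id not in doc.input_types:  # spike sources serialize once
            out.append(_serialize_component(cell))
    for syn in doc.synapse_types.values():
        out.append(_serialize_component(syn))
    for inp in doc.input_types.values():
        out.append(_serialize_component(inp))
    for net in doc.networks.values():
        out.append(f'  <network id="{net.id}">')
        for p in net.populations:
            out.append(f'    <population id="{p.id}" component="{p.component}" size="{p.size}"/>')
        chem = [c for c in net.connections if not c.electrical]
        elec = [c for c in net.connections if c.electrical]
        for i, c in enumerate(chem):
            out.append(f'    <projection id="proj{i}" synapse="{c.synapse}" '
                       f'presynapticPopulation="{c.pre_pop}" '
                       f'postsynapticPopulation="{c.post_pop}">')
            out.append(
                f'      <connectionWD id="0" preCellId="../{c.pre_pop}/{c.pre_inst}/x" '
                f'postCellId="../{c.post_pop}/{c.post_inst}/x" '
                f'preSegmentId="{c.pre_seg}" preFractionAlong="{c.pre_frac!r}" '
                f'postSegmentId="{c.post_seg}" postFractionAlong="{c.post_frac!r}" '
                f'weight="{c.weight!r}" delay="{c.delay!r}s"/>'
            )
            out.append("    </projection>")
        for i, c in enumerate(elec):
            out.append(f'    <electricalProjection id="eproj{i}" '
                       f'presynapticPopulation="{c.pre_pop}" '
                       f'postsynapticPopulation="{c.post_pop}">')
            out.append(
                f'      <electricalConnectionInstanceW id="0" preCell="{c.pre_inst}" '
                f'postCell="{c.post_inst}" preSegment="{c.pre_seg}" '
                f'postSegment="{c.post_seg}" preFractionAlong="{c.pre_frac!r}" '
                f'postFractionAlong="{c.post_frac!r}" weight="{c.weight!r}" '
                f'synapse="{c.synapse}"/>'
            )
            out.append("    </electricalProjection>")
        by_list: dict[tuple[str, str], list[InputAttachment]] = {}
        for ia in net.inputs:
            by_list.setdefault((ia.component, ia.population), []).append(ia)
        for li, ((comp, pop), items) in enumerate(by_list.items()):
            out.append(f'    <inputList id="il{li}" component="{comp}" population="{pop}">')
            for j, ia in enumerate(items):
                out.append(
                    f'      <inputW id="{j}" target="../{pop}/{ia.instance}/x" '
                    f'segmentId="{ia.segment}" fractionAlong="{ia.fraction!r}" '
                    f'weight="{ia.weight!r}"/>'
                )
            out.append("    </inputList>")
        out.append("  </network>")
    out.append("</neuroml>")
    return "\n".join(out) + "\n"


def serialize_simulation(spec: SimulationSpec, model_file: str) -> str:
    """Emit a LEMS ``<Simulation>`` document that includes ``model_file``."""
    out = [
        "<Lems>",
        f'  <Include file="{model_file}"/>',
        '  <Target component="sim1"/>',
        f'  <Simulation id="sim1" length="{spec.duration!r}s" '
        f'step="{spec.dt!r}s" target="{spec.target}" seed="{spec.seed}">',
    ]
    for i, of in enumerate(spec.output_files):
        out.append(f'    <OutputFile id="of{i}" fileName="{of.path}">')
        for j, c in enumerate(of.columns):
            out.append(f'      <OutputColumn id="c{j}" quantity="{c}"/>')
        out.append("    </OutputFile>")
    for i, ef in enumerate(spec.event_files):
        out.append(f'    <EventOutputFile id="ef{i}" fileName="{ef.path}" format="{ef.format}">')
        for j, s in enumerate(ef.selections):
            out.append(f'      <EventSelection id="{j}" select="{s}" eventPort="{ef.port}"/>')
        out.append("    </EventOutputFile>")
    out.append("  </Simulation>")
    out.append("</Lems>")
    return "\n".join(out) + "\n"
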