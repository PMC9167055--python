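"""Numeric runtime shared by generated kernels and the interpreted oracle.

Precision contract
------------------
Expressions are evaluated in IEEE double precision; every *named* assigned
variable and every state-variable store is rounded to 32-bit precision through
:func:`f32` (the default mode), while simulated time and anything derived from
it stays in double precision. In full-double mode the rounding step is the
identity. Both the generated kernels and the interpreted reference simulator
route every statement through the same rounding hook, so the two execution
paths perform bit-identical arithmetic in either mode.

RNG contract
------------
Every stochastic element (Poisson-firing synapse, Poisson spike generator,
``random()`` in LEMS expressions) owns a counter-based stream keyed by
``(global seed, neuron index, element index)``. Streams are independent of
worker count and of work-item execution order, which is what makes
multi-worker runs bit-identical to single-worker runs.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "f32",
    "f64_identity",
    "FUNCTIONS",
    "explin",
    "heaviside",
    "uniform_stream",
    "neuron_stream",
]


def f32(x: float) -> float:
    """Round a double to the nearest binary32 value (returned as a double)."""
    return float(np.float32(x))


def f64_identity(x: float) -> float:
    return x


def heaviside(x: float) -> float:
    # numpy convention: H(0) = 0.5
    if x > 0.0:
        return 1.0
    if x == 0.0:
        return 0.5
    return 0.0


def explin(x: float) -> float:
    """x / (1 - exp(-x)) with the removable singularity at 0 filled in.

    Used by the exponential-linear HH rate form; the |x| < 1e-9 guard keeps
    the rate finite and smooth where v crosses the midpoint exactly.
    """
    if abs(x) < 1e-9:
        return 1.0 / (1.0 - x / 2.0)
    return x / (1.0 - math.exp(-x))


# Function table for LEMS expressions. `ln` and `log` are both the natural
# logarithm (jLEMS convention).
FUNCTIONS = {
    "exp": math.exp,
    "ln": math.log,
    "log": math.log,
    "sqrt": math.sqrt,
    "abs": abs,
    "sin": math.sin,
    "cos": math.cos,
    "tanh": math.tanh,
    "H": heaviside,
    "explin": explin,
}


_STREAM_KIND_INPUT = 0x706F6973  # per-step uniforms for Poisson elements
_STREAM_KIND_NEURON = 0x72616E64  # random() draws inside LEMS dynamics


def uniform_stream(seed: int, neuron: int, element: int, n: int) -> np.ndarray:
    """The per-step uniform[0,1) sequence of one stochastic element.

    Counter-based (Philox): the whole sequence is a pure function of the key,
    so any consumer — engine kernel, oracle, any worker — sees the same draws.
    """
    key = ((int(seed) & 0x7FFFFFFF) | (_STREAM_KIND_INPUT << 32),
           (int(neuron) << 32) | int(element))
    return np.random.Generator(np.random.Philox(key=key)).random(n)


def neuron_stream(seed: int, neuron: int) -> np.random.Generator:
    """Sequential stream backing ``random(x)`` in LEMS expressions.

    Draw order within a neuron is fixed by statement order; neurons never
    share a stream, so execution order across neurons cannot matter.
    """
    key = ((int(seed) & 0x7FFFFFFF) | (_STREAM_KIND_NEURON << 32),
           int(neuron))
    return np.random.Generator(np.random.Philox(key=key))
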