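"""Exception hierarchy shared by all flatbrain stages."""


class ModelError(Exception):
    """Base class for model definition / analysis problems (CLI exit code 2)."""


class UnresolvedReference(ModelError):
    pass


class UnsupportedElement(ModelError):
    pass


class UnknownUnit(ModelError):
    pass


class DimensionMismatch(ModelError):
    pass


class CyclicDerivedVariables(ModelError):
    pass


class UnknownFunction(ModelError):
    pass


class UnsupportedLemsFeature(ModelError):
    pass


class MissingSimulation(ModelError):
    pass


class UnresolvedProbePath(ModelError):
    pass


class CyclicMorphology(ModelError):
    pass


class MissingBiophysics(ModelError):
    pass


class UnboundRequirement(ModelError):
    pass


class CyclicExposureDependency(ModelError):
    pass


class OffsetOverflow(ModelError):
    pass


class GenerationBug(Exception):
    """A generated kernel failed to compile; carries a source excerpt."""


class NumericalBlowup(Exception):
    """A state variable became non-finite (CLI exit code 3)."""

    def __init__(self, step: int, where: str):
        super().__init__(f"non-finite state at step {step}: {where}")
        self.step = step
        self.where = where


class SingularSystem(Exception):
    pass


class InsufficientSpikes(ValueError):
    pass


class DegenerateRange(ValueError):
    pass


class ZeroPooledVariance(ValueError):
    pass


class FrameLengthMismatch(Exception):
    pass


class DanglingSentinel(Exception):
    pass


class ProtocolTimeout(Exception):
    """Send-list exchange failed to terminate (deadlock guard)."""
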