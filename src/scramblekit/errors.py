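"""Exception hierarchy.

Every failure mode of the analysis raises a subclass of
:class:`ScrambleKitError`, so callers (including the CLI) can distinguish
user/data errors from genuine bugs.
"""


class ScrambleKitError(Exception):
    """Base class for all scramblekit errors."""


class ParseError(ScrambleKitError):
    """A structure/trajectory/window file could not be parsed.

    Carries the offending line number where known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ValidationError(ScrambleKitError):
    """Input data violates an invariant (duplicate ids, bad roles, ...)."""


class ParameterError(ScrambleKitError):
    """A parameter value is out of its legal domain."""


class EmptySelectionError(ScrambleKitError):
    """A selection required to be non-empty matched no particles."""


class EmptyCylinderError(ScrambleKitError):
    """No membrane particles inside the local-center cylinder."""


class UnsupportedBoxError(ScrambleKitError):
    """Triclinic (non-orthorhombic) box encountered."""


class DegenerateGeometryError(ScrambleKitError):
    """Coordinate set too degenerate (collinear, n < 3) for superposition."""


class ConvergenceError(ScrambleKitError):
    """Self-consistent iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class ConnectivityError(ScrambleKitError):
    """Zero-count gap splits the sampled CV range; WHAM cannot bridge it."""


class DomainError(ScrambleKitError):
    """Profile/series does not cover the domain an operation requires."""


class RangeError(ScrambleKitError):
    """A sample fell outside the histogram range."""
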