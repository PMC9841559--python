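"""Exception hierarchy.

Two families matter downstream: :class:`ValidationError` (bad inputs,
malformed files, parameter violations) and :class:`NumericalError`
(instability, divergence, non-convergence).  The CLI maps each family to a
distinct exit code.
"""

from __future__ import annotations


class TautodynError(Exception):
    """Base class for all package errors."""


class ValidationError(TautodynError):
    """Invalid input data or parameters."""


class MalformedPathError(ValidationError):
    """Reaction-path coordinates are not strictly increasing."""


class InsufficientDataError(ValidationError):
    """Too few images/frames to proceed."""


class PathParseError(ValidationError):
    """A path-table file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"{message} (line {line})")
        self.line = line


class DomainError(ValidationError):
    """Query outside the interpolation or grid domain."""


class NoBarrierError(ValidationError):
    """Profile has no interior maximum between terminal minima."""


class InvalidWindowError(ValidationError):
    """Requested sub-path window does not contain the transition state."""


class ParameterError(ValidationError):
    """Scalar parameter outside its allowed range."""


class SelectionError(ValidationError):
    """Atom selections of frame and reference do not match."""


class MissingGeometryError(ValidationError):
    """Operation requires per-image geometries the path does not carry."""


class SpecError(ValidationError):
    """Synthetic-data specification is infeasible or inconsistent."""


class EmptyInputError(ValidationError):
    """An empty series/trajectory where at least one element is required."""


class InvalidWellError(ValidationError):
    """Well window does not contain a usable potential minimum."""


class UndefinedCompetitionError(ValidationError):
    """Branching fraction of two zero rates is undefined."""


class NumericalError(TautodynError):
    """Numerical failure during propagation or rate extraction."""


class StabilityError(NumericalError):
    """Time step too large for the grid (advection would alias)."""


class DivergenceError(NumericalError):
    """NaN/Inf encountered during propagation; names the step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message if step is None else f"{message} (step {step})")
        self.step = step


class NonConvergenceError(NumericalError):
    """No rate plateau within the time horizon; carries the partial series."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class UnderflowError(NumericalError):
    """Rate below the reliably measurable floor; use an analytic estimate."""


class RangeError(NumericalError):
    """Result outside the representable double range."""
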