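"""Exception and warning types shared across the pipeline."""


class NotchdynError(Exception):
    """Base class for all package errors."""


class ParameterError(NotchdynError, ValueError):
    """A model or pipeline parameter violates its constraints."""


class TopologyError(NotchdynError, ValueError):
    """A cell-neighbor map is malformed (e.g. a cell with no neighbors)."""


class SolverError(NotchdynError, RuntimeError):
    """ODE integration failed or produced non-finite state."""


class DataError(NotchdynError, ValueError):
    """Input data violate a precondition (too few samples, empty group, ...)."""


class SchemaError(DataError):
    """A table is missing required columns or has malformed rows."""


class BoundaryUndefinedError(NotchdynError, RuntimeError):
    """No equal-posterior crossing exists between the two mixture means."""


class FitWarning(UserWarning):
    """A model fit is degenerate or suspicious but still returned."""
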