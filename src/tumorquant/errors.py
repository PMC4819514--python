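"""Exception hierarchy.

``UndefinedResultError`` signals a metric whose mathematical definition has no
value for the given input (e.g. a perfused-vessel fraction with zero vessel
pixels). It is deliberately distinct from ``InvalidInputError`` — callers may
catch it and record "undefined" rather than a number.
"""


class TumorquantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TumorquantError, ValueError):
    """Input violates a documented precondition."""


class UndefinedResultError(TumorquantError):
    """The requested quantity is mathematically undefined for this input."""


class DegenerateDataError(TumorquantError):
    """Data admit no meaningful fit (e.g. zero variance everywhere in ANOVA)."""
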