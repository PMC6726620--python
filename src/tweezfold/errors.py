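"""Exception hierarchy for tweezfold."""


class TweezfoldError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(TweezfoldError, ValueError):
    """Pulling/clamp protocol or kinetic parameters out of their valid domain."""


class InvalidInputError(TweezfoldError, ValueError):
    """A function argument violates its precondition."""


class NumericalError(TweezfoldError, ArithmeticError):
    """A solver failed to converge."""


class FormatError(TweezfoldError, ValueError):
    """A trace/result file is malformed (missing or bad header)."""


class ValidationError(TweezfoldError, ValueError):
    """File contents violate a trace invariant (reports the offending line)."""


class SchemaError(TweezfoldError, ValueError):
    """A result record is missing a required field."""


class IllConditionedFitError(TweezfoldError, ValueError):
    """Fit input is degenerate (e.g. no force spread for a WLC fit)."""


class TooShortTraceError(TweezfoldError, ValueError):
    """Trace shorter than the smoothing/detection window."""


class MissingGroupError(TweezfoldError, KeyError):
    """Aggregation requested for a domain with no events."""


class EmptyHistogramError(TweezfoldError, ValueError):
    """Histogram requested over zero events."""


class DegenerateTraceError(TweezfoldError, ValueError):
    """Hopping trace never visits two distinguishable states."""


class UnidentifiableModelError(TweezfoldError, ValueError):
    """Binding-model fit has no information on one or more parameters."""


class IncompleteDesignError(TweezfoldError, KeyError):
    """Energy dissection is missing a required construct/condition row."""


class InvalidGeometryError(TweezfoldError, ValueError):
    """Structure-derived quantity is non-physical (e.g. ΔLc ≤ 0)."""
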