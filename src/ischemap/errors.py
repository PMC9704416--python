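"""Exception hierarchy shared across the pipeline."""


class IschemapError(Exception):
    """Base class for all package errors."""


class ValidationError(IschemapError, ValueError):
    """An input value violates a documented precondition."""


class DimensionError(IschemapError, ValueError):
    """Array shapes are inconsistent with the requested operation."""


class SpecError(IschemapError, ValueError):
    """A network specification does not match its declared role."""


class StateError(IschemapError, RuntimeError):
    """An operation was called on an object in the wrong state (e.g. untrained)."""


class DivergenceError(IschemapError, RuntimeError):
    """Training produced a non-finite loss; the message names the offending term."""
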