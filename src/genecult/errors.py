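"""Exception types shared across the package."""


class GenecultError(Exception):
    """Base class for all package errors."""


class SchemaError(GenecultError):
    """An input file does not have the documented column layout."""


class ValidationError(GenecultError):
    """A record violates a data invariant (e.g. genotype counts not summing to n)."""


class DomainError(GenecultError):
    """A parameter is outside the mathematical domain of an operation."""


class LayoutMismatchError(GenecultError):
    """Two summary-statistic vectors do not share the same coordinate layout."""
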