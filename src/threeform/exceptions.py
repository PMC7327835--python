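"""Exception hierarchy shared across the package."""


class ThreeFormError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(ThreeFormError, ValueError):
    """A design specification or item pool violates its invariants."""


class CoverageRetryError(ThreeFormError, RuntimeError):
    """RIA retries exhausted without producing an X-block covering every scale."""


class SchemaError(ThreeFormError, ValueError):
    """A data table does not match the schema implied by a design or form set."""


class EstimationError(ThreeFormError, RuntimeError):
    """Estimation cannot proceed (e.g. a fully missing column)."""


class UnderIdentifiedError(EstimationError):
    """A factor model was requested with fewer than three indicators."""


class InvalidInputError(ThreeFormError, ValueError):
    """Numerically invalid input to a statistic (zero SE, zero truth, ...)."""
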