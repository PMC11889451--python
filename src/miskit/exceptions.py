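"""Exception hierarchy for miskit.

All errors raised by the library derive from :class:`MiskitError` so callers
can catch one base class at a pipeline boundary (e.g. the CLI).
"""


class MiskitError(Exception):
    """Base class for all miskit errors."""


class ParseError(MiskitError):
    """A CSV cell could not be interpreted as a number or missing token."""


class InsufficientDataError(MiskitError):
    """Too few usable observations for the requested procedure."""


class DegenerateDataError(MiskitError):
    """Input is degenerate (constant vector, singular covariance, ...)."""


class UnusableFeatureError(MiskitError):
    """A feature has no observed values and cannot be used."""


class NotApplicableError(MiskitError):
    """The requested test has nothing to test (e.g. no missing data)."""


class ContractError(MiskitError):
    """Two objects passed together do not satisfy the documented contract."""


class ValidationError(MiskitError):
    """A parameter violates its documented bounds."""
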