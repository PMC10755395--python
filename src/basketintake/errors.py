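"""Exception hierarchy.

Every stage raises a subclass of :class:`BasketIntakeError` so pipeline
callers can distinguish configuration mistakes, bad input data and
statistical degeneracies from programming errors.
"""


class BasketIntakeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BasketIntakeError):
    """A configuration value is invalid; the message names the field."""


class DataError(BasketIntakeError):
    """An input record violates the documented schema or invariants."""


class UnknownProductError(DataError):
    """A transaction line references a product id absent from the catalogue."""


class TableCoverageError(BasketIntakeError):
    """An age falls outside the energy-recommendation table's bands."""


class UndefinedCompositionError(BasketIntakeError):
    """Energy-adjusted measures are undefined at zero or negative energy."""


class InsufficientDataError(BasketIntakeError):
    """Too few (valid) observations for the requested statistic."""


class SingularDesignError(BasketIntakeError):
    """The regression design is singular (no spread in the mean-of-logs)."""


class UndefinedCorrelationError(BasketIntakeError):
    """Correlation is undefined when either measure has zero variance."""
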