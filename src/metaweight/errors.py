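"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`MetaweightError`, so callers can catch one type at pipeline
boundaries while tests target the specific subclass.
"""


class MetaweightError(Exception):
    """Base class for all errors raised by metaweight."""


class SchemaError(MetaweightError):
    """An input table is missing a mandatory column."""


class RowParseError(MetaweightError):
    """A row of an input table could not be parsed; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateRecordError(MetaweightError):
    """Two records share the (dataset_id, predictor, outcome) key."""


class ConfigurationError(MetaweightError):
    """A merge map, corpus spec, or run config is internally inconsistent."""


class DomainError(MetaweightError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConversionError(DomainError):
    """A beta coefficient converts to a correlation outside (-1, 1)."""


class InsufficientDataError(MetaweightError):
    """Too few effects for the requested analysis (k below the minimum)."""


class SingularDesignError(MetaweightError):
    """Regression design matrix is singular (e.g. all precisions equal)."""


class ConvergenceError(MetaweightError):
    """An iterative procedure failed to stabilise; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
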