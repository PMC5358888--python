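"""Exception hierarchy shared across the pipeline.

Every error raised on a contract violation derives from :class:`RBCForecastError`
so callers (and the CLI) can distinguish pipeline failures from programming
errors. Subclasses map to error classes: malformed input files, incomplete
measurement grids, out-of-domain values, dangling identifier references,
too-little data for an estimator, misaligned time grids, and unsupported model
configurations.
"""


class RBCForecastError(Exception):
    """Base class for all pipeline errors."""


class DataFormatError(RBCForecastError):
    """Input file does not conform to the expected tabular dialect."""


class IncompleteDataError(RBCForecastError):
    """A (metabolite, replicate, time) cell is missing from the grid."""


class DomainError(RBCForecastError):
    """A value violates its domain (e.g. negative concentration)."""


class UnknownIdentifierError(RBCForecastError):
    """An identifier references nothing in the dataset (or is ambiguous)."""


class InsufficientDataError(RBCForecastError):
    """Too few replicates, samples, or time points for the operation."""


class AlignmentError(RBCForecastError):
    """Time grids of series that must share a grid do not match."""


class UnsupportedSpecError(RBCForecastError):
    """A model specification outside the supported estimation family."""


class SpecError(RBCForecastError):
    """An invalid synthetic-data or run specification."""


class UsageError(RBCForecastError):
    """An operation invoked in a way its contract forbids."""
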