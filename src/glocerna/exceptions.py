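"""Exception hierarchy.

Every error raised by this package derives from :class:`GlocernaError`, so
callers can catch a single type at pipeline boundaries while tests assert
the specific failure mode.
"""


class GlocernaError(Exception):
    """Base class for all package errors."""


class FileFormatError(GlocernaError):
    """A file violates the expected tabular layout (duplicate ids, missing
    columns, empty gene-set lines, ...)."""


class PairingError(GlocernaError):
    """A patient lacks exactly one normal and one tumor sample column."""


class ValidationError(GlocernaError):
    """A value violates a domain invariant (negative expression,
    non-positive survival time, bad strand, start >= end)."""


class ConsistencyError(GlocernaError):
    """Internally inconsistent inputs (a target with two classes, shared
    count exceeding the marginals, universe smaller than observed sets)."""


class DomainError(GlocernaError):
    """A mathematical operation is undefined for the input, e.g. log2 of a
    non-positive value; the message suggests a pseudocount."""


class GeneLookupError(GlocernaError, KeyError):
    """A requested gene id is absent from the expression matrix."""


class CohortSizeError(GlocernaError):
    """Fewer matched samples than the method requires (n < 3)."""


class UndefinedCorrelationError(GlocernaError):
    """Pearson correlation undefined (zero variance in a gene row); the
    pair must be excluded, never silently scored 0."""


class DegenerateGroupingError(GlocernaError):
    """Mean-expression dichotomization produced an empty group."""


class UndefinedTestError(GlocernaError):
    """A statistical test is undefined for the data (e.g. log-rank with
    zero events)."""


class ConfigError(GlocernaError):
    """Invalid configuration (infeasible synthetic counts, bad cutoffs)."""
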