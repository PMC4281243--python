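"""Exception hierarchy.

Input problems (bad files, bad values) raise :class:`DataError` subclasses;
misconfiguration raises :class:`ConfigError` subclasses.  The CLI maps the two
branches to distinct exit codes.
"""


class TissuespecError(Exception):
    """Base class for all package errors."""


class ConfigError(TissuespecError):
    """Invalid configuration (thresholds, simulation settings, pipeline config)."""


class DataError(TissuespecError):
    """Invalid input data."""


class MissingFileError(DataError):
    """An input file does not exist."""


class NonNumericValueError(DataError):
    """An expression cell could not be parsed as a number."""


class DuplicateGeneError(DataError):
    """A gene identifier occurs more than once in an expression table."""


class NegativeValueError(DataError):
    """A negative value where only non-negative quantities are meaningful."""


class MetadataError(DataError):
    """Sample metadata inconsistent with the expression matrix."""


class AnnotationError(DataError):
    """An immunohistochemistry annotation record fails validation."""


class ConsistencyError(TissuespecError):
    """Internal bookkeeping failed a consistency check (signals a bug)."""
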