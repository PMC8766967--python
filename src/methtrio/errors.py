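"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`MethtrioError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class MethtrioError(Exception):
    """Base class for all methtrio domain errors."""


class FormatError(MethtrioError):
    """A file could not be parsed as the expected tabular format."""


class BetaValidationError(MethtrioError):
    """A beta value violated the [0, 1] bound or matrix invariants."""


class DesignError(MethtrioError):
    """A trio design is incomplete, duplicated or inconsistent."""


class VocabularyError(MethtrioError):
    """A categorical token is outside its closed vocabulary."""


class AnnotationError(MethtrioError):
    """A probe annotation table violates its invariants."""


class SingularFitError(MethtrioError):
    """The mixture design matrix is (numerically) rank deficient."""


class DataError(MethtrioError):
    """Not enough usable data for the requested computation."""


class ConfigError(MethtrioError):
    """A configuration value is out of range or inconsistent."""


class DegenerateDistributionError(MethtrioError):
    """A distribution-level computation met zero spread."""
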