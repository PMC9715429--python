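"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`ForamShiftError`, so callers can catch one base class at pipeline
level while tests can assert on the specific subclass.
"""


class ForamShiftError(Exception):
    """Base class for all package errors."""


class FormatError(ForamShiftError):
    """A table is missing required columns or is otherwise malformed."""


class ValidationError(ForamShiftError):
    """Data violate an invariant (negative abundance, tied ages, ...)."""


class UnknownTaxonError(ForamShiftError):
    """A column label is neither canonical nor covered by a merge rule."""


class DegenerateSampleError(ForamShiftError):
    """An all-zero abundance vector where a composition is required."""


class EmptyReferenceError(ForamShiftError):
    """An analogue reference set ended up with no samples."""


class CoverageError(ForamShiftError):
    """A time series does not span the requested interpolation window."""


class InsufficientDataError(ForamShiftError):
    """Too few points for the requested fit (regression, LOESS, ranks)."""


class ConfigError(ForamShiftError):
    """Invalid run or simulation configuration."""


class ExtentError(ForamShiftError):
    """A sample falls outside the requested grid extent."""
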