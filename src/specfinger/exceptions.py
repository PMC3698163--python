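"""Exception hierarchy.

Every error raised by the package derives from :class:`SpecFingerError`,
so callers can catch one type at a pipeline boundary while tests can
assert on the specific failure mode.
"""


class SpecFingerError(Exception):
    """Base class for all package errors."""


class FormatError(SpecFingerError):
    """Malformed input file (ragged rows, unparseable cells)."""


class GridError(SpecFingerError):
    """Wavenumber grid is non-monotone, non-uniform, or incompatible."""


class IdentityError(SpecFingerError):
    """Duplicate or missing sample identifiers."""


class RegionError(SpecFingerError):
    """Spectral region invalid or does not intersect the grid."""


class DegenerateInputError(SpecFingerError):
    """Input with no usable variation (constant spectrum or column)."""


class CohortError(SpecFingerError):
    """Cohort composition insufficient for the requested operation."""


class SelectionError(SpecFingerError):
    """Feature selection cannot proceed (e.g. all scores zero)."""


class TrainingError(SpecFingerError):
    """Neural-network session failed (non-finite loss etc.)."""


class EvaluationError(SpecFingerError):
    """Classification metrics undefined for the given summaries."""


class ConfigError(SpecFingerError):
    """Invalid configuration values."""
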