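"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`DolphinError` so callers can catch the whole family at once.
"""


class DolphinError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(DolphinError):
    """Rows of a multiple alignment do not all have the same length."""


class AlignmentValidationError(DolphinError):
    """An alignment contains characters outside the recognized alphabet."""


class EmptyInputError(DolphinError):
    """A file or collection that must be non-empty is empty."""


class EmptyAfterFilterError(DolphinError):
    """Taxonomic filtering removed every sequence of an alignment."""


class LookupFailedError(DolphinError):
    """A sequence id, protein id or matrix key could not be resolved."""


class OutOfRangeError(DolphinError):
    """A residue or column index falls outside its valid range."""


class ParameterError(DolphinError):
    """An invalid parameter value (e.g. non-positive pseudo-count)."""


class UnsupportedResidueError(DolphinError):
    """A residue letter outside the 20-letter amino-acid alphabet."""


class UnsupportedVariantError(DolphinError):
    """A variant that is not a simple missense substitution."""


class HgvsParseError(DolphinError):
    """A string that does not parse as HGVS p. substitution notation."""


class ReferenceMismatchError(DolphinError):
    """The alignment residue disagrees with the variant's stated wild type."""


class BackgroundError(DolphinError):
    """An invalid or inconsistent background frequency table."""


class ValidationError(DolphinError):
    """Generic tabular-input validation failure (e.g. allele frequency > 1)."""


class SchemaError(DolphinError):
    """A tabular input is missing required columns."""


class FitError(DolphinError):
    """Zone-model fitting failed (degenerate input)."""


class NotFittedError(DolphinError):
    """A zone model was used before fitting/loading."""


class PairingError(DolphinError):
    """Label and prediction sequences have different lengths."""


class ReportError(DolphinError):
    """A report was requested over an empty denominator."""
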