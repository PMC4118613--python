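"""Exception hierarchy for the full-sib QTL pipeline."""


class FsqtlError(Exception):
    """Base class for all package errors."""


class ParseError(FsqtlError):
    """A pipeline input file violates its dialect.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class MarkerNotUsable(FsqtlError):
    """A marker cannot support a single-marker fit; scans skip it."""


class NotSegregatingError(MarkerNotUsable):
    """Fewer than two genotype classes observed among usable individuals."""


class SparseClassError(MarkerNotUsable):
    """Some legal genotype class has fewer observations than ``min_class_n``."""


class IncompleteClassesError(MarkerNotUsable):
    """A class mean required by the effect decomposition is missing."""


class DegenerateFitError(FsqtlError):
    """Residual variance is zero; the normal likelihood is unbounded."""
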