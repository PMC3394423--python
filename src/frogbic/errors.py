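"""Exception hierarchy shared across the package."""


class FrogbicError(Exception):
    """Base class for all package-specific errors."""


class MatrixParseError(FrogbicError):
    """Raised when an expression-matrix file is malformed (ragged rows, bad tokens)."""


class ValidationError(FrogbicError):
    """Raised when a domain object violates its invariants (duplicate ids, n<2 ...)."""


class ParameterError(FrogbicError):
    """Raised for out-of-range or inconsistent user parameters."""


class EncodingError(FrogbicError):
    """Raised for malformed binary bicluster encodings."""


class DegenerateBiclusterError(FrogbicError):
    """Raised when a statistic is requested for an empty gene or condition set."""
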