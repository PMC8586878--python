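"""Exception hierarchy shared across the package."""


class SparsekmError(Exception):
    """Base class for all package errors."""


class ValidationError(SparsekmError, ValueError):
    """Raised when an input matrix, label file, or array triple is malformed."""


class UnsupportedFormat(SparsekmError, ValueError):
    """Raised for file contents the readers deliberately refuse (e.g. complex mtx)."""


class DegenerateInputError(SparsekmError, ValueError):
    """Raised when a probability-based divergence is requested on a row that has
    no probability interpretation (zero total count and no prior)."""


class NoMassError(SparsekmError, ValueError):
    """Raised when weighted sampling is asked to draw from an all-zero weight vector."""
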