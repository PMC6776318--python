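"""Exception types shared across the package."""


class RareQtlError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(RareQtlError, ValueError):
    """Raised when an input carries no usable signal (constant predictor,
    all-zero weights, constant counts, ...)."""


class EmptyRegionError(RareQtlError, ValueError):
    """Raised when no variants survive filtering in the tested region."""


class RankDeficientError(RareQtlError, ValueError):
    """Raised when a regression design matrix is not of full column rank."""


class ConvergenceError(RareQtlError, RuntimeError):
    """Raised when an iterative fit fails irrecoverably."""
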