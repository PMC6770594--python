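"""Exception hierarchy shared across the package.

Every error raised by library code derives from :class:`BenfordExprError`
so the CLI can turn any failure into a clean nonzero exit.
"""


class BenfordExprError(Exception):
    """Base class for all errors raised by benfordexpr."""


class DigitDomainError(BenfordExprError, ValueError):
    """A value has no first significant digit (non-positive, NaN, infinite)."""


class EmptyDistributionError(BenfordExprError, ValueError):
    """A digit histogram with no usable values cannot be normalized/tested."""


class NormalizationError(BenfordExprError, ValueError):
    """Median-ratio normalization is undefined for the given matrix."""


class EmptyPanelError(BenfordExprError, ValueError):
    """Panel selection produced no eligible genes."""


class PipelineError(BenfordExprError, RuntimeError):
    """End-to-end classification pipeline failure (names group/mode)."""


class MatrixParseError(BenfordExprError, ValueError):
    """Malformed expression matrix or label file."""
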