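"""Exception hierarchy shared across the pipeline stages."""


class HemotexError(Exception):
    """Base class for all package errors."""


class ParameterError(HemotexError, ValueError):
    """A scalar parameter is outside its valid range."""


class ValidationError(HemotexError, ValueError):
    """Structured input violates a documented invariant."""


class FormatError(HemotexError, ValueError):
    """A file parsed but its content is unsupported (bit depth, dims, ...)."""


class GenerationError(HemotexError, ValueError):
    """Phantom geometry is infeasible for the requested image size."""


class DegenerateHistogramError(HemotexError, ValueError):
    """Otsu thresholding needs at least two occupied histogram bins."""
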