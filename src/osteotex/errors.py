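"""Exception types shared across the pipeline."""


class OsteotexError(Exception):
    """Base class for all package-specific errors."""


class InputError(OsteotexError, ValueError):
    """Missing, corrupt, or inconsistent input data."""


class EmptyROIError(OsteotexError, ValueError):
    """A region of interest contains no usable pixels (or pixel pairs)."""


class FitError(OsteotexError, RuntimeError):
    """A model fit failed to converge or produced non-finite parameters."""
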