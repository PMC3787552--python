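"""Exception hierarchy shared across the package."""


class LvmorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LvmorphError, ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateHistogramError(LvmorphError, ValueError):
    """Otsu thresholding was asked to split a constant gray-level set."""


class EmptyContourError(LvmorphError, RuntimeError):
    """A level-set evolution collapsed to an empty region."""


class AliasingError(ValidationError):
    """A requested velocity meets or exceeds the venc, which would wrap the phase."""
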