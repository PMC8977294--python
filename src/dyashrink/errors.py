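"""Exception hierarchy for dyashrink."""


class DyashrinkError(Exception):
    """Base class for all package errors."""


class InvalidImageError(DyashrinkError):
    """Image contains non-finite values or has degenerate dimensions."""


class InvalidFilterError(DyashrinkError):
    """Filter tap sequence is empty or otherwise unusable."""


class ScaleLimitError(DyashrinkError):
    """Requested decomposition depth exceeds what the image size supports."""


class InvalidDecompositionError(DyashrinkError):
    """Decomposition planes are mutually inconsistent."""


class InvalidParameterError(DyashrinkError):
    """A numeric parameter is outside its valid domain."""


class InvalidSpecError(DyashrinkError):
    """A phantom or noise specification is invalid."""


class UndefinedSNRError(DyashrinkError):
    """SNR is undefined: zero error energy or zero signal energy."""


class UnsupportedFormatError(DyashrinkError):
    """Image file format or layout not supported (e.g. multi-channel color)."""
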