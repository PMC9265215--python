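"""Exception hierarchy for rtmc."""


class RtmcError(Exception):
    """Base class for all rtmc errors."""


class ParameterError(RtmcError, ValueError):
    """An argument or configuration value is invalid; names the offending field."""


class DimensionError(RtmcError, ValueError):
    """Array shapes are incompatible (frame vs kernel, frame vs template, ...)."""


class InputError(RtmcError, ValueError):
    """Input data is empty, mismatched in length, or otherwise unusable."""


class GeometryError(RtmcError, ValueError):
    """An ROI or crop does not fit inside the frame."""


class DegenerateInputError(RtmcError, ValueError):
    """A correlation map is empty or fully masked; no displacement can be estimated."""


class UndefinedCorrelationError(RtmcError, ValueError):
    """Correlation is undefined because a patch has zero variance."""


class StreamError(RtmcError, RuntimeError):
    """A frame stream violated its contract (e.g. geometry change mid-stream)."""


class UnsupportedFormatError(RtmcError, ValueError):
    """The requested movie container/codec is not supported."""
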