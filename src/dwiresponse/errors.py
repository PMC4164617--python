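"""Exception hierarchy shared across the package."""


class DWIResponseError(Exception):
    """Base class for all package errors."""


class ValidationError(DWIResponseError):
    """Input violates a documented precondition or invariant."""


class FormatError(DWIResponseError):
    """On-disk data does not match the expected file format."""


class ConsistencyError(DWIResponseError):
    """Redundant fields disagree beyond tolerance (e.g. stored vs. recomputed deltas)."""


class DegenerateInputError(DWIResponseError):
    """Input is structurally valid but carries no usable information
    (constant image, zero-variance sample, singular scatter matrix)."""


class EmptyVOIError(DWIResponseError):
    """A volume-of-interest statistic was requested on an empty mask or
    a mask containing no valid voxels."""
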