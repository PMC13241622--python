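"""Exception hierarchy shared across the package.

Validation errors (bad config, bad input shapes) are kept distinct from
runtime failures so the CLI can map them to different exit codes.
"""


class NanoclusterError(Exception):
    """Base class for all package errors."""


class ValidationError(NanoclusterError):
    """Invalid parameter or input (shape mismatch, out-of-range value)."""


class SchemaError(ValidationError):
    """A delimited file is missing required columns."""


class UnsupportedFormatError(ValidationError):
    """An image file is not a single-plane integer greyscale image."""


class EmptySignalError(NanoclusterError):
    """The analyzed region contains no intensity to threshold."""


class PlacementError(NanoclusterError):
    """Scene synthesis could not place all clusters at the requested spacing."""


class InferenceError(NanoclusterError):
    """Group comparison requested on a degenerate design (e.g. one animal)."""
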