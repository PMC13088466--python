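"""Exception types shared across the package."""


class RootspecError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RootspecError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(RootspecError):
    """White/dark reference frames cannot calibrate the cube."""


class SegmentationError(RootspecError):
    """Root/background separation or grid partitioning failed."""


class FormatError(RootspecError):
    """A file on disk is inconsistent or missing required metadata."""
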