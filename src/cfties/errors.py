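"""Exception types shared across the package."""


class CfTiesError(Exception):
    """Base class for all package errors."""


class BedParseError(CfTiesError, ValueError):
    """A BED-style file could not be parsed; message names the offending line."""


class ValidationError(CfTiesError, ValueError):
    """An input (config, sample sheet, count matrix, ...) failed validation."""


class UnquantifiableSampleError(CfTiesError, RuntimeError):
    """A sample's housekeeping (DHS) reference signal is not positive, so
    depth-normalised signals cannot be formed for it."""


class PartialScoreError(CfTiesError, RuntimeError):
    """A sample is missing one of the assays required for the integrated score.
    The message names the missing mark."""


class PlacementError(CfTiesError, RuntimeError):
    """The synthetic site placer could not satisfy its overlap constraints."""
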