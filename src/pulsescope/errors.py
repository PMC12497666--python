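"""Exception hierarchy.

All package-specific failures derive from :class:`PulseScopeError` so callers
can catch one base class; subclasses mirror the failure modes of the pipeline
stages (file format, rendering, estimation, sequence structure).
"""


class PulseScopeError(Exception):
    """Base class for all pulsescope errors."""


class FormatError(PulseScopeError):
    """A file does not have the expected layout (e.g. wrong channel count)."""


class UnsupportedFormatError(FormatError):
    """A file uses an encoding the reader does not handle (e.g. non-PCM WAV)."""


class RangeError(PulseScopeError):
    """Sample values fall outside the representable full-scale range."""


class ResolutionError(PulseScopeError):
    """A pulse is too short to be represented at the given sample rate."""


class ClippingError(PulseScopeError):
    """Rendered signal would exceed full scale after gain."""


class EstimationError(PulseScopeError):
    """A frequency/offset estimate could not be formed from the data."""


class MeasurementError(PulseScopeError):
    """A pulse measurement was requested on a degenerate interval."""


class ClassificationError(PulseScopeError):
    """A pulse segment is too short to classify."""


class StructureError(PulseScopeError):
    """Events do not exhibit the sequence structure required by an analysis."""


class FixtureLookupError(PulseScopeError, KeyError):
    """Unknown packaged fixture name."""


class NoPulsesWarning(UserWarning):
    """Emitted when detection finds no events above the noise floor."""
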