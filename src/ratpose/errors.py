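"""Exception hierarchy for ratpose.

All package-specific failures derive from :class:`RatposeError` so callers can
catch one base class at CLI boundaries.
"""


class RatposeError(Exception):
    """Base class for all ratpose errors."""


class ConfigurationError(RatposeError):
    """A config object violates its invariants."""


class GenerationError(RatposeError):
    """Synthetic image/video generation failed (e.g. scene too small)."""


class SchemaError(RatposeError):
    """An annotation file violates the JSON schema."""


class SplitError(RatposeError):
    """The dataset cannot be partitioned as requested."""


class FormatError(RatposeError):
    """A trajectory or report file is malformed."""


class EncodeError(RatposeError):
    """A landmark cannot be encoded onto the heatmap grid."""


class DecodeError(RatposeError):
    """A heatmap channel cannot be decoded to a coordinate."""


class BuildError(RatposeError):
    """A model cannot be constructed for the requested configuration."""


class ShapeError(RatposeError):
    """An input tensor has the wrong shape for the model."""


class TrainingError(RatposeError):
    """Training diverged or was misconfigured."""


class EvaluationError(RatposeError):
    """Predictions and labels cannot be compared."""
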