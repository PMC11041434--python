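"""Exception hierarchy for gripscreen."""


class GripscreenError(Exception):
    """Base class for all gripscreen errors."""


class SchemaError(GripscreenError, ValueError):
    """A recording or manifest does not conform to the 229-channel schema."""


class ParseError(GripscreenError, ValueError):
    """A recording file contains an unparseable value."""


class RecordingValidationError(GripscreenError, ValueError):
    """A recording failed validation where a valid one was required."""


class InsufficientLengthError(GripscreenError, ValueError):
    """Recording too short for 64-frame segmentation."""


class DomainError(GripscreenError, ValueError):
    """A kinematic input is outside its physical domain."""


class DesignError(GripscreenError, ValueError):
    """Sample construction violated the experiment design contract."""


class DegenerateTrainingError(GripscreenError, ValueError):
    """Training data cannot support a binary classifier (single class, too few samples)."""


class DimensionError(GripscreenError, ValueError):
    """Feature dimensionality mismatch between model and samples."""


class ConfigurationError(GripscreenError, ValueError):
    """Invalid cross-validation or experiment configuration."""


class UndefinedROCError(GripscreenError, ValueError):
    """ROC analysis requested with only one class present."""
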