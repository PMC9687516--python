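"""Shared exception and warning types for the pipeline."""


class EotrhTextureError(Exception):
    """Base class for all package errors."""


class ValidationError(EotrhTextureError, ValueError):
    """Input data violates a documented invariant (bad grade, empty ROI, ...)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class BoundsError(ValidationError):
    """A rectangle or window does not fit inside its image."""


class ParameterError(EotrhTextureError, ValueError):
    """A free parameter is outside its documented domain."""


class DegenerateInputWarning(UserWarning):
    """Emitted when an input is degenerate (e.g. constant image, zero variance)
    and the operation falls back to its documented degenerate value."""
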