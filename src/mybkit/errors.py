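"""Exception types shared across the toolkit."""


class MybkitError(Exception):
    """Base class for all toolkit errors."""


class SequenceValidationError(MybkitError):
    """A sequence contains characters outside the accepted alphabet."""


class ConfigurationError(MybkitError):
    """A parameter value is outside its valid range."""


class SizeError(MybkitError):
    """An input collection is too small for the requested operation."""


class GFFParseError(MybkitError):
    """A GFF3 record could not be interpreted."""


class ReconciliationError(MybkitError):
    """Identifier spaces of two inputs could not be joined."""


class LookupError_(MybkitError):
    """A requested identifier is absent from the input."""


class GenerationError(MybkitError):
    """A synthetic-data specification cannot be realised."""


class StageError(MybkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
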