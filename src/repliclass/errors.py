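"""Exception hierarchy shared across the package."""


class RepliclassError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RepliclassError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(RepliclassError, ValueError):
    """A text stream (FASTA header, BLAST tabular line, ...) is malformed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class BackendError(RepliclassError, RuntimeError):
    """An external dependency (e.g. the blastn binary) is missing or failed."""


class ModelStateError(RepliclassError, RuntimeError):
    """A model was used before fitting, or a persisted model is unusable."""


class ModelFormatError(ModelStateError):
    """A persisted model file is corrupt or has an incompatible version."""
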