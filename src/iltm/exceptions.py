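"""Package-specific exception types."""


class TrainingError(RuntimeError):
    """Raised when model training diverges (non-finite loss)."""


class DegenerateTrainingError(TrainingError):
    """Raised when every position of every training sequence is masked."""


class ContextLengthError(ValueError):
    """Raised when a token sequence exceeds the transformer context."""
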