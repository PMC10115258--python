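"""Exception types shared across the pipeline."""


class FourhzError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(FourhzError, ValueError):
    """An argument violates an operation's precondition."""


class InsufficientDataError(FourhzError, ValueError):
    """Input too short / too few events for the requested estimate."""


class DegenerateInputError(FourhzError, ValueError):
    """Input is degenerate (e.g. constant signal) for this operation."""


class SchemaError(FourhzError, ValueError):
    """Session container does not match the expected schema."""
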