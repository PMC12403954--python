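"""Exception types shared across the package."""


class SustainzError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SustainzError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateDataError(SustainzError, ValueError):
    """Input data are degenerate for the requested operation.

    Examples: zero residual variance in the control sample, a constant
    variable handed to a rank test, a rank-deficient design matrix.
    """


class SchemaError(SustainzError, ValueError):
    """A table does not conform to the declared column schema."""


class PipelineError(SustainzError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
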