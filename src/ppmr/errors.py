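"""Exception hierarchy for the PPMR pipeline.

Every error carries a short machine-readable ``code`` that also appears in
drop logs, so exclusions and failures can be audited after a run.
"""


class PipelineError(Exception):
    """Base class; ``code`` is a stable, kebab-case reason string."""

    code = "pipeline-error"

    def __init__(self, message: str = "", **context):
        super().__init__(message or self.code)
        self.context = context


class InsufficientLWDataError(PipelineError):
    code = "insufficient-LW-data"


class InvalidMeasurementError(PipelineError):
    code = "invalid-measurement"


class NoPreyError(PipelineError):
    code = "no-prey"


class InvalidResponseError(PipelineError):
    code = "invalid-response"


class InvalidDesignError(PipelineError):
    code = "invalid-design"


class NoConvergenceError(PipelineError):
    code = "no-convergence"

    def __init__(self, message: str = "", diagnostics=None, **context):
        super().__init__(message, **context)
        self.diagnostics = diagnostics


class UnknownGroupError(PipelineError):
    code = "unknown-group"


class NoBiomassError(PipelineError):
    code = "no-biomass"


class InvalidConfigError(PipelineError):
    code = "invalid-config"


class InvalidPPMRError(PipelineError):
    code = "invalid-ppmr"


class SchemaError(PipelineError):
    code = "schema-error"
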