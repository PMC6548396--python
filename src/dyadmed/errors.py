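"""Exception hierarchy shared across the package."""


class DyadmedError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DyadmedError):
    """Input does not match the expected layout (wrong item count, bad role label...)."""


class RangeError(DyadmedError):
    """A value lies outside its admissible range (e.g. a Likert item not in 1..6)."""


class MissingItemError(DyadmedError):
    """A required item response is absent; the message names the item."""


class ConfigError(DyadmedError):
    """A simulation or pipeline configuration violates its invariants."""


class EstimationError(DyadmedError):
    """Model estimation cannot proceed (rank deficiency, too few dyads...)."""


class ConvergenceError(EstimationError):
    """The discrepancy-function optimizer failed to converge.

    Carries the best discrepancy value and gradient norm reached.
    """

    def __init__(self, message: str, best_discrepancy: float, grad_norm: float):
        super().__init__(message)
        self.best_discrepancy = best_discrepancy
        self.grad_norm = grad_norm


class UndefinedStatisticError(DyadmedError):
    """A statistic is undefined for the given inputs (RMSEA at df=0, proportion
    mediated with a zero total effect)."""


class PipelineError(DyadmedError):
    """A pipeline stage failed; names the stage and offending context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
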