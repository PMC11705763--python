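"""Exception hierarchy for statecall.

Every failure mode surfaced to callers derives from :class:`StatecallError`
so that pipeline stages can distinguish our diagnostics from programming
errors.
"""


class StatecallError(Exception):
    """Base class for all statecall diagnostics."""


class DegenerateInputError(StatecallError, ValueError):
    """Input data cannot support the requested fit (too few positive
    values, zero variance, flat density)."""


class InitializationError(StatecallError, ValueError):
    """EM initialization failed, typically because too few housekeeping
    genes were found in the expression vector."""


class NonConvergenceError(StatecallError, RuntimeError):
    """EM collapsed or failed to converge after all restarts.

    Carries a ``diagnostics`` dict with the last parameter values and
    restart count.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidFitError(StatecallError, ValueError):
    """A MixtureFit with non-finite or invariant-violating parameters was
    supplied to a downstream computation."""


class DomainError(StatecallError, ValueError):
    """A value outside its mathematical domain (e.g. negative TPM)."""


class ParameterError(StatecallError, ValueError):
    """A user-supplied parameter outside its documented domain."""


class ShapeError(StatecallError, ValueError):
    """Mismatched gene/sample dimensions between related containers."""


class MappingError(StatecallError, KeyError):
    """Samples present in a matrix without a tissue/cohort label."""


class IncompleteAtlasError(StatecallError, ValueError):
    """A (gene, tissue) summary required for dormancy calling is missing."""


class AnnotationError(StatecallError, ValueError):
    """A gene lacks the genomic intervals needed for reference labelling."""


class EvaluationError(StatecallError, ValueError):
    """Predictions and reference standard share no usable genes."""


class FormatError(StatecallError, ValueError):
    """A file does not parse under its declared dialect."""


class ConfigError(StatecallError, ValueError):
    """An infeasible or inconsistent run/simulation configuration."""
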