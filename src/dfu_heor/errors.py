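"""Exception hierarchy.

Validation failures (bad probabilities, forbidden transitions, malformed
parameter files) raise :class:`ValidationError`; out-of-domain arguments raise
:class:`DomainError`; a threshold search with no sign change raises
:class:`NoThresholdError` carrying diagnostics.
"""


class DfuHeorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DfuHeorError, ValueError):
    """A parameter set or input table violates a model invariant."""


class StructuralViolationError(ValidationError):
    """Probability mass placed on a transition the model structure forbids."""


class DomainError(DfuHeorError, ValueError):
    """An argument lies outside its mathematical domain."""


class NoThresholdError(DfuHeorError, RuntimeError):
    """The threshold search found no sign change of net monetary benefit.

    Attributes
    ----------
    diagnostics : dict
        NMB values at the bracket endpoints and the settings used, to help
        the caller understand why no effect size can reach the target ICER.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
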