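"""Exception hierarchy for model and fitting errors."""


class DimerstabError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DimerstabError, ValueError):
    """A model parameter violates its physical domain (e.g. K_D <= 0)."""


class InvalidInputError(DimerstabError, ValueError):
    """Input data violate a documented precondition."""


class FitFailureError(DimerstabError, RuntimeError):
    """A nonlinear fit did not converge or the data admit no transition.

    Carries per-start diagnostics when multi-start optimization was used.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NoDecayError(FitFailureError):
    """A trace shows no resolvable decay above the noise floor."""
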