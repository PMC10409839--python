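"""Exception hierarchy shared across the package."""


class CipredictError(Exception):
    """Base class for all package-specific errors."""

    #: short machine-readable category used by the CLI
    category = "error"


class ValidationError(CipredictError):
    """An input value violates a contract (range, attainability, schema)."""

    category = "validation"


class FitFailureError(CipredictError):
    """Maximum-likelihood refit did not produce identifiable coefficients."""

    category = "fit-failure"

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GenerationError(CipredictError):
    """The synthetic-cohort generator could not satisfy its constraints."""

    category = "generation"


class MissingEndpointError(CipredictError):
    """A follow-up series lacks the visit a computation requires."""

    category = "missing-endpoint"
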