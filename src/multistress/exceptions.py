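"""Exception hierarchy for the multistress package."""


class MultistressError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MultistressError):
    """An input table is missing a required column or has an unusable header."""


class ValidationError(MultistressError, ValueError):
    """A record violates an invariant (counts, signs, ranges).

    Carries ``row`` (0-based index into the offending table) when the
    violation is attributable to a single record.
    """

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class DomainError(MultistressError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class FitError(MultistressError):
    """Dose-response optimisation failed or the data cannot support the model.

    ``diagnostics`` holds the optimizer result or a description of the
    degeneracy for post-mortem inspection.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ConfigurationError(MultistressError):
    """A run configuration or comparison design is inconsistent with the data."""
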