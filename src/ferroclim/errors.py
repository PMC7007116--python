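"""Exception hierarchy shared by all pipeline stages."""


class FerroclimError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(FerroclimError):
    """An input file does not match its documented column schema."""


class ValidationError(FerroclimError, ValueError):
    """A record violates a documented invariant (negative supply, duplicate key, ...)."""


class DomainError(FerroclimError, ValueError):
    """An operation was called with inputs outside its mathematical domain."""


class FoodLookupError(FerroclimError, KeyError):
    """A food referenced by a table is missing from the catalog."""


class FitError(FerroclimError):
    """A skew-normal fit could not reproduce the requested quantiles."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class ConfigurationError(FerroclimError):
    """The run or effects configuration is incomplete or inconsistent."""


class ScenarioError(FerroclimError):
    """A counterfactual diet cannot be constructed for a country."""


class AlignmentError(FerroclimError):
    """Two result sets that must share a country set do not."""
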