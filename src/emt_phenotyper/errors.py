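"""Exception hierarchy shared across the pipeline stages."""


class EMTPhenotyperError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EMTPhenotyperError, ValueError):
    """An input value or specification violates a documented precondition."""


class PlacementError(EMTPhenotyperError):
    """Requested cells could not be placed without forbidden overlap."""


class DegenerateObjectError(EMTPhenotyperError):
    """A segmented object is too small to measure reliably (< 5 px)."""


class HousekeepingError(ValidationError):
    """Housekeeping band intensity / Ct is missing or non-positive."""


class FitError(EMTPhenotyperError):
    """Regression cannot be fitted (too few points or constant abscissa)."""


class JoinError(EMTPhenotyperError, KeyError):
    """Condition keys of two stage outputs do not match."""

    def __init__(self, message: str, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


class ConfigError(ValidationError):
    """Run configuration is missing, malformed or references absent paths."""
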