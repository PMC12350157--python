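"""Exception hierarchy.

Errors are categorized so the CLI can map them to exit codes:
config errors (bad parameters), data errors (bad inputs), and
numeric errors (estimation failures).
"""


class PacniError(Exception):
    """Base class for all package errors."""


class ConfigError(PacniError):
    """Invalid configuration or parameter values."""


class SchemaError(PacniError):
    """Feature schema violates its invariants (duplicates, unknown classes...)."""


class DataError(PacniError):
    """Input data violates a precondition."""


class ParseError(DataError):
    """A cell or record could not be parsed; carries row/column context."""


class IncompleteFeaturesError(DataError):
    """A feature vector is missing required schema features."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(
            message or f"missing required features: {', '.join(self.missing)}"
        )


class DegenerateDataError(DataError):
    """Zero-variance stratum or otherwise degenerate input."""


class InsufficientLongitudinalDataError(DataError):
    """No subject has the repeated observations a longitudinal fit needs."""


class NumericError(PacniError):
    """Estimation failed to converge or produced non-finite results."""
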