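"""Exception hierarchy for the iamtox pipeline.

Errors are split into input/schema problems (``InputError``) and
numerical/degenerate-design problems (``NumericalError``) so the CLI can map
them to distinct exit codes.
"""


class IamtoxError(Exception):
    """Base class for all package errors."""


class InputError(IamtoxError):
    """Bad input data or schema (CLI exit code 2)."""


class SchemaError(InputError):
    """A required column is missing or a vocabulary is violated."""


class ParseError(InputError):
    """A cell could not be parsed as the expected type."""


class PairingError(InputError):
    """Observed/predicted (or records/scores) sequences do not align."""


class MissingDescriptorError(InputError):
    """A compound lacks the descriptor a model requires."""


class GroupingError(InputError):
    """Reports with mixed endpoints were given to a single comparison."""


class NumericalError(IamtoxError):
    """Degenerate or insufficient numerical input (CLI exit code 3)."""


class DegenerateDesignError(NumericalError):
    """Design matrix is singular (e.g. constant descriptor)."""


class InsufficientDataError(NumericalError):
    """Too few observations for the requested computation."""


class UndefinedMetricError(NumericalError):
    """The metric is undefined for this input (e.g. zero-mean observed)."""
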