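"""Exception hierarchy for the DQS pipeline.

Every stage raises a subclass of :class:`DQSError`, so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class DQSError(Exception):
    """Base class for all errors raised by dqscore."""


class SchemaError(DQSError):
    """An input table is missing required columns or is structurally invalid."""


class UniquenessError(SchemaError):
    """A column that must be unique (e.g. item_id) contains duplicates."""


class ValidationError(DQSError):
    """A value violates a domain invariant (negative amount, weight 0, ...)."""


class CompositionLookupError(DQSError):
    """An intake event references an item_id with no composition row."""

    def __init__(self, item_id: str):
        self.item_id = item_id
        super().__init__(f"no composition entry for item_id {item_id!r}")


class ConfigurationError(DQSError):
    """A scoring rule or model was configured inconsistently."""


class AlignmentError(DQSError):
    """Two paired inputs do not cover the same participants."""


class InsufficientDataError(DQSError):
    """Too few observations for the requested statistic."""


class ConvergenceError(DQSError):
    """A model fit failed to converge (e.g. quasi-complete separation)."""
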