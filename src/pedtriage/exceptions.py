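"""Package-specific exception types."""


class PedtriageError(Exception):
    """Base class for all package errors."""


class CohortParseError(PedtriageError):
    """A cohort or vocabulary CSV row failed validation.

    Carries the offending row number (1-based, header excluded) and field
    name so malformed registry extracts can be located quickly.
    """

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, field '{field}': {message}")


class UnresolvableScoreError(PedtriageError):
    """No diagnosis code on a record could be resolved against the score table."""


class DegenerateLabelsError(PedtriageError):
    """ROC analysis requires at least one positive and one negative label."""


class DegenerateGroupError(PedtriageError):
    """A descriptive comparison group is empty."""
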