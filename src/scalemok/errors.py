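"""Exception hierarchy for scalemok."""


class ScalemokError(Exception):
    """Base class for all scalemok errors."""


class ConfigurationError(ScalemokError):
    """Invalid configuration: unknown column, malformed mapping, bad grid."""


class ParseError(ScalemokError):
    """A cell in the input could not be parsed as an integer response."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class EmptyDataError(ScalemokError):
    """No complete cases remain for the requested analysis."""


class DegenerateItemError(ScalemokError):
    """An item (or margin) has zero variance, so H is undefined for it."""

    def __init__(self, message: str, items: list[str] | None = None):
        super().__init__(message)
        self.items = items or []


class UndefinedReliabilityError(ScalemokError):
    """Total-score variance is zero; internal consistency is undefined."""
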