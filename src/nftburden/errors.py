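"""Exception hierarchy shared across the package."""


class NFTBurdenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NFTBurdenError):
    """An input file does not conform to the expected schema."""


class RowParseError(FormatError):
    """A single row of a delimited file could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class GeometryError(NFTBurdenError):
    """A polygon is invalid (self-intersecting, degenerate, zero area)."""


class DomainError(NFTBurdenError, ValueError):
    """An argument is outside the operation's mathematical domain."""


class LabelingError(NFTBurdenError):
    """Cognitive status cannot be derived from the available inputs."""


class SeparationError(NFTBurdenError):
    """Logistic fit failed due to (quasi-)complete separation."""


class DesignError(NFTBurdenError):
    """A factorial design is unusable (e.g. an empty cell)."""


class ConfigError(NFTBurdenError):
    """Pipeline configuration failed validation; carries all messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
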