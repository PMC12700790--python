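"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3,
anything else -> 1.
"""


class TrioDnvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrioDnvError):
    """Invalid configuration: bad thresholds, missing samples, unknown tools."""


class DataError(TrioDnvError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")
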