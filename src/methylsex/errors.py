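"""Exception hierarchy.

Configuration problems (bad thresholds, missing groups, overlapping
train/test ids) raise :class:`ConfigurationError`; malformed or
inconsistent data raise :class:`DataError`.  The CLI maps these to exit
codes 2 and 3 respectively.
"""


class MethylsexError(Exception):
    """Base class for package errors."""


class ConfigurationError(MethylsexError):
    """A parameter or run configuration is invalid."""

    exit_code = 2


class DataError(MethylsexError):
    """Input data are malformed or internally inconsistent."""

    exit_code = 3


class SizingError(ConfigurationError):
    """A requested genomic element does not fit where it was placed."""


class ParseError(DataError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
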