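"""Exception hierarchy shared across the package."""


class BrushtrackError(Exception):
    """Base class for all package-specific errors."""


class AreaCodeFormatError(BrushtrackError, ValueError):
    """Raised when an area code string is not 4 decimal digits."""


class AreaCodeValidationError(BrushtrackError, ValueError):
    """Raised when a syntactically valid code names an impossible area."""


class StreamParseError(BrushtrackError, ValueError):
    """Raised on malformed session-stream files; carries the offending line."""

    def __init__(self, message, line=None, path=None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += f" [{path}]"
        if line is not None:
            loc += f" (line {line})"
        super().__init__(message + loc)


class PairingError(BrushtrackError, ValueError):
    """Raised when two interval streams cannot be paired (metadata mismatch)."""


class DegenerateDataError(BrushtrackError, ValueError):
    """Raised when a statistic is requested on data that cannot support it."""


class UndefinedResultError(BrushtrackError, ValueError):
    """Raised when a quantity is mathematically undefined for the input."""
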