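"""Exception hierarchy.

All package-specific failures derive from :class:`MicrosyntaxError` so callers
can catch the whole family; each subclass also derives from the matching
built-in so generic handlers keep working.
"""


class MicrosyntaxError(Exception):
    """Base class for all microsyntax errors."""


class SequenceLengthError(MicrosyntaxError, ValueError):
    """Sequence too short for the requested operation (e.g. word length k)."""


class DegenerateSequenceError(MicrosyntaxError, ValueError):
    """An operation produced or received an empty / unusable sequence."""


class UndefinedSampleEntropyError(MicrosyntaxError, ValueError):
    """No k-word recurs (B = 0): SE(k) is undefined, which is distinct from
    the +infinity case (recurrences exist but none extends, A = 0)."""


class ModelError(MicrosyntaxError, ValueError):
    """A transition model violates its invariants (row sums, shapes, ...)."""


class GenerationError(MicrosyntaxError, RuntimeError):
    """Surrogate/chain generation cannot continue (e.g. absorbing zero row)."""


class ConfigError(MicrosyntaxError, ValueError):
    """Invalid generator configuration."""


class DomainError(MicrosyntaxError, ValueError):
    """Argument outside the mathematical domain of a normalized measure."""


class ParseError(MicrosyntaxError, ValueError):
    """A label file or manifest failed to parse.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
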