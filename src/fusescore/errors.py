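"""Exception hierarchy shared across the package."""


class FuseScoreError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(FuseScoreError):
    """A record or cell violates a domain invariant."""


class ConfigError(FuseScoreError):
    """A configuration file or argument is malformed."""


class TableParseError(FuseScoreError):
    """A persisted table could not be parsed.

    Carries an optional 1-based ``line`` attribute pointing at the
    offending line of the file.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ScoreLatticeError(FuseScoreError):
    """A total score fell inside a class gap that half-integer weights
    can never produce — indicates a misconfigured weight set."""
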