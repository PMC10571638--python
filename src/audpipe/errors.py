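"""Exception hierarchy for audpipe.

All package errors derive from :class:`AudpipeError` so callers (and the CLI)
can distinguish validation problems from programming errors.
"""


class AudpipeError(Exception):
    """Base class for all audpipe errors."""


class ParseError(AudpipeError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(AudpipeError):
    """An event log violated a structural invariant."""


class ScheduleError(AudpipeError):
    """A phase schedule (or phase slice) has the wrong shape for an analysis."""


class PhaseLookupError(AudpipeError, KeyError):
    """A requested phase occurrence does not exist in the schedule."""


class AnimalLookupError(AudpipeError, KeyError):
    """A requested animal is absent from a log or registry."""


class ConfigError(AudpipeError, ValueError):
    """Invalid configuration (simulator, ladder, scoring)."""


class ScoringError(AudpipeError):
    """Scoring cannot proceed (population too small, zero-variance column)."""


class DomainError(AudpipeError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class DegenerateColumnWarning(UserWarning):
    """A behavior column has zero variance; no animal can satisfy it."""


class CompletenessWarning(UserWarning):
    """Animals missing from a scored phase were excluded from the matrix."""
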