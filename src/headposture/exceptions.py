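"""Exception hierarchy for headposture.

All library-raised errors derive from :class:`HeadPostureError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class HeadPostureError(Exception):
    """Base class for all headposture errors."""


class InvalidRotationError(HeadPostureError):
    """A matrix claimed to be a rotation is not orthonormal (or det != +1)."""


class BehindCameraError(HeadPostureError):
    """A model point has non-positive camera-frame depth and cannot project."""


class DegenerateConfigurationError(HeadPostureError):
    """Visible landmarks are too few or geometrically degenerate for a fit."""


class NotTrackedError(HeadPostureError):
    """A quantity was requested from an estimate that did not track."""


class AlignmentError(HeadPostureError):
    """Two per-frame series do not align by frame_id."""


class EmptySummaryError(HeadPostureError):
    """No frames survive filtering; a summary would be vacuous."""


class InsufficientRepeatsError(HeadPostureError):
    """Not enough repeated observations of a pose for the reliability matrix."""


class UndefinedStatisticError(HeadPostureError):
    """A statistic is undefined for the input (e.g. zero-variance series)."""


class ParseError(HeadPostureError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(HeadPostureError):
    """A run-configuration file is invalid (unknown key, bad type/value)."""
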