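"""Exception hierarchy.

Exit codes mirror the CLI contract: 2 for data/validation problems, 3 for
stage-order violations, 4 for anything else.
"""


class AdaptrialError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ValidationError(AdaptrialError):
    """Malformed or contract-violating input data."""

    exit_code = 2


class EmptyWeekError(ValidationError):
    """A GP-week with zero relevant consultations; the outcome fraction is undefined."""


class BaselineUndefinedError(ValidationError):
    """A clinic (or GP) has no relevant consultations over the whole baseline stage."""


class AllocationIntegrityError(ValidationError):
    """Submitted tallies contradict the stored allocation plan."""


class DuplicateWeekError(ValidationError):
    """A week's tallies were already ingested."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class StageOrderError(AdaptrialError):
    """An operation was invoked in the wrong trial stage."""

    exit_code = 3


class UnsupportedOperationError(AdaptrialError):
    """Operation requires information (e.g. ground truth) that is unavailable."""
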