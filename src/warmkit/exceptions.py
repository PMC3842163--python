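"""Exception hierarchy.

``WarmkitError`` marks user-facing input/data problems (CLI exit code 1);
anything else escaping a command is an internal error (exit code 2).
"""


class WarmkitError(ValueError):
    """Base class for invalid inputs or data that cannot be analysed."""


class InsufficientDataError(WarmkitError):
    """Too few frames / too short a record for the requested operation."""


class DegenerateSignalError(WarmkitError):
    """A signal with no usable information (all zero, flat, or non-positive)."""


class QualityWarning(UserWarning):
    """Non-fatal data-quality issue (e.g. many frames excluded from a log fit)."""
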