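"""Exception hierarchy.

Validation problems (bad input files, inconsistent labels, out-of-domain
parameters) and computation problems (degenerate data reaching a numeric
stage) are distinguished so the CLI can map them to distinct exit codes.
"""


class FetoquantError(Exception):
    """Base class for all package errors."""


class ValidationError(FetoquantError):
    """Invalid arguments, malformed files, or inconsistent metadata."""


class SchemaError(ValidationError):
    """A required column is missing or has the wrong type."""


class ComputationError(FetoquantError):
    """A numeric stage cannot proceed (degenerate or insufficient data)."""


class InsufficientCalibrationError(ComputationError):
    """Too few calibration points survived filtering to fit a curve."""
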