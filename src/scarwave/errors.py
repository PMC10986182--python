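"""Exception hierarchy.

Exit-code mapping in the CLI distinguishes config (2), numeric (3) and
I/O (4) failures; keep new exceptions under the matching base class.
"""


class ScarwaveError(Exception):
    """Base class for all package errors."""


class ConfigError(ScarwaveError):
    """Invalid specification, parameters or study configuration."""


class InvalidSpecError(ConfigError):
    """A synthetic-data spec violates its invariants."""


class DimensionError(ConfigError):
    """Mismatched array/mesh sizes."""


class NumericalError(ScarwaveError):
    """Numerical failure during integration or fitting."""


class BlowUpError(NumericalError):
    """NaN/Inf encountered while stepping; carries time and variable name."""

    def __init__(self, message, time_ms=None, variable=None):
        super().__init__(message)
        self.time_ms = time_ms
        self.variable = variable


class CalibrationError(NumericalError):
    """Conduction-velocity target unreachable on the calibration cable."""


class PropagationFailureError(NumericalError):
    """Planar wave failed to traverse the calibration cable."""


class IOFormatError(ScarwaveError):
    """Malformed input file; carries line/offset context in the message."""
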