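"""Exception hierarchy shared across the package."""


class PahteqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PahteqError):
    """Invalid configuration (simulation or pipeline)."""


class InputError(PahteqError):
    """Invalid or inconsistent input data (missing control, label mismatch...)."""


class SchemaError(InputError):
    """Tabular input does not match its declared schema."""


class ExtrapolationError(PahteqError):
    """Requested effect level lies outside the observed dose-response range."""


class CalibrationError(PahteqError):
    """Calibration-curve fit failed (too few levels, non-positive slope)."""
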