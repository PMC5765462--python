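"""Exception types shared across the package."""


class AirbreathError(Exception):
    """Base class for package errors."""


class CalibrationError(AirbreathError):
    """Air-volume calibration received physically inconsistent readings."""


class InsufficientDataError(AirbreathError):
    """Too few samples/observations for the requested computation."""


class UndefinedStatisticError(AirbreathError):
    """The statistic has no defined value for this input (e.g. CD of an
    empty event stream, proximity fraction with zero breaths)."""


class UnidentifiableError(AirbreathError):
    """The model cannot separate the requested variance components from
    the data at hand (e.g. repeatability with one observation per id)."""


class SchemaError(AirbreathError):
    """An input table is missing required columns or has bad values."""
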