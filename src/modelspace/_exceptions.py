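"""Exception hierarchy for modelspace."""


class ModelSpaceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ModelSpaceError):
    """Invalid configuration (dimension mismatch, out-of-range parameter)."""


class DataError(ModelSpaceError):
    """Invalid numeric input (NaN design entries, asymmetric covariance)."""


class SchemaError(ModelSpaceError):
    """Malformed cohort table (missing columns, duplicate rows, bad indices)."""


class CalibrationError(ModelSpaceError):
    """Prevalence calibration could not reach the requested target."""
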