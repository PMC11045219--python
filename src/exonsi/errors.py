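"""Exception hierarchy shared across the pipeline."""


class ExonsiError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ExonsiError, ValueError):
    """An argument is outside its legal domain."""


class FormatError(ExonsiError, ValueError):
    """An on-disk file violates its format contract."""


class DataError(ExonsiError, ValueError):
    """In-memory tables are inconsistent with each other."""


class CalibrationError(ExonsiError, RuntimeError):
    """A correction factor cannot be estimated from the control data."""
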