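"""Exception hierarchy shared across the package."""


class PhStatError(Exception):
    """Base class for all package errors."""


class GeometryError(PhStatError):
    """Digit geometry does not fit the frame, or is internally inconsistent."""


class CalibrationError(PhStatError):
    """OCR or pump calibration could not be established."""


class CapacityError(PhStatError):
    """A syringe dose would exceed the remaining syringe capacity."""


class ProtocolError(PhStatError):
    """A wire-protocol line could not be parsed."""

    def __init__(self, message: str, line: str | None = None):
        super().__init__(message)
        self.line = line


class LogParseError(PhStatError):
    """A CSV log row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class ConfigError(PhStatError):
    """Experiment configuration is missing sections or fails validation."""


class TitrationTimeout(PhStatError):
    """pH never stabilised within the allowed wait; carries the partial curve."""

    def __init__(self, message: str, partial_curve=None):
        super().__init__(message)
        self.partial_curve = partial_curve


class UnreliableDoseWarning(UserWarning):
    """Requested peristaltic dose is below the pump's reliable minimum."""
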