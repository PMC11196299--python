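"""Exception hierarchy shared by all piezosleep modules."""


class PiezosleepError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PiezosleepError):
    """A text input could not be parsed; the message names the offending row."""


class RangeError(PiezosleepError):
    """A sensor value lies outside the 24-bit dynamic range of the ADC."""


class EmptyInputError(PiezosleepError):
    """An input file or sequence contained no usable data."""


class LengthError(PiezosleepError):
    """A signal is too short for the requested operation."""


class ConfigurationError(PiezosleepError):
    """Invalid parameter combination (band above Nyquist, empty grid, ...)."""


class DomainError(PiezosleepError):
    """An argument lies outside its mathematical domain (negative rate, ...)."""


class OrderingError(PiezosleepError):
    """Timestamps that must be strictly increasing are not."""


class InsufficientDataError(PiezosleepError):
    """Not enough valid data to compute a statistic (e.g. < 10 min of beats)."""


class UndefinedCorrelationError(PiezosleepError):
    """Correlation requested on a constant vector."""


class SingularityError(PiezosleepError):
    """Collinear predictors in a regression design matrix."""


class SaturationError(PiezosleepError):
    """A simulated signal would exceed the 24-bit ADC range."""
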