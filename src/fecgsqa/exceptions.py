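"""Package-wide exception types."""


class FecgSqaError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FecgSqaError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class DegenerateSignalError(FecgSqaError, ValueError):
    """A constant / zero signal where a non-degenerate one is required."""


class NotTrainedError(FecgSqaError, RuntimeError):
    """A model was used before it was trained or labeled."""
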