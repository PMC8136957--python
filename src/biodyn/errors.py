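"""Exception hierarchy shared across the package."""


class BiodynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BiodynError, ValueError):
    """A simulation or pipeline configuration field is invalid."""


class DataError(BiodynError, ValueError):
    """Input data do not satisfy an operation's preconditions."""


class RangeError(BiodynError, ValueError):
    """A requested analysis window falls outside the recording."""


class ComputationError(BiodynError, ArithmeticError):
    """A quantity is undefined for the given input (e.g. zero mean)."""


class StatisticsError(BiodynError, ValueError):
    """A statistical operation received degenerate input (e.g. one class)."""


class FormatError(BiodynError, ValueError):
    """A file container does not follow the expected layout."""
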