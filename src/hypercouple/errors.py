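"""Exception hierarchy.

Configuration problems map to CLI exit code 2, data problems to exit code 3.
"""


class HypercoupleError(Exception):
    """Base class for all package errors."""


class ConfigError(HypercoupleError):
    """Invalid configuration (bad parameter values, unknown config keys)."""


class DataError(HypercoupleError):
    """Invalid or inconsistent input data."""


class AlignmentError(DataError):
    """Trial/epoch axes or TFR axes do not line up between inputs."""


class FormatError(DataError):
    """A file does not conform to its documented on-disk layout."""


class DomainError(DataError):
    """A numeric argument is outside the operation's valid domain."""


class SelectionError(DataError):
    """A channel/frequency/time selection is empty or out of range."""


class DegenerateBaselineError(DataError):
    """Baseline power is zero somewhere; relative change undefined."""


class ConstantInputError(DataError):
    """Correlation of an all-constant vector is undefined."""


class SingularDesignError(DataError):
    """Regression design matrix is rank deficient."""
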