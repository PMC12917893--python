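"""Exception hierarchy.

CLI exit-code mapping: ConfigurationError -> 2, DataQualityError -> 3,
TrainingDivergenceError -> 4; everything else is an ordinary failure (1).
"""


class AfbnpError(Exception):
    """Base class for package errors."""


class ConfigurationError(AfbnpError):
    """Invalid configuration value or unknown option."""


class InputFormatError(AfbnpError):
    """Malformed input data (e.g. unsorted R-peak timestamps)."""


class DataQualityError(AfbnpError):
    """Recording rejected by the signal-quality gate."""


class InsufficientDataError(AfbnpError):
    """Not enough data for the requested computation."""


class TrainingDivergenceError(AfbnpError):
    """Non-finite loss encountered during optimisation."""


class ContractViolationError(AfbnpError):
    """An internal invariant (fold hygiene, scaler/fold pairing) was broken."""
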