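"""Exception types shared across the package."""


class MineError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MineError, ValueError):
    """Raised for inputs that carry no usable signal (e.g. zero variance)."""


class InsufficientDataError(MineError, ValueError):
    """Raised when a trace is too short for the requested operation."""


class TrainingError(MineError, RuntimeError):
    """Raised when network optimization diverges (non-finite loss)."""


class ConfigError(MineError, ValueError):
    """Raised for invalid or unknown configuration values."""


class UndefinedScoreError(MineError, ArithmeticError):
    """Raised when a variance-explained score has a vanishing denominator."""
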