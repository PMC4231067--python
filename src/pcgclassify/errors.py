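"""Exception hierarchy shared across the package."""


class PCGError(Exception):
    """Base class for all pcgclassify errors."""


class InputError(PCGError, ValueError):
    """A caller supplied data that violates an operation's preconditions."""


class ConfigurationError(PCGError, ValueError):
    """A configuration value is outside its admissible range."""


class TrainingError(PCGError, RuntimeError):
    """A classifier could not be trained on the given data."""


class InvalidGenomeError(PCGError, ValueError):
    """A decoded genome cannot produce a trainable ensemble (e.g. empty mask)."""


class UndefinedMetricError(PCGError, ArithmeticError):
    """A metric's denominator is zero; raised rather than silently returning 0."""


class NumericalError(PCGError, ArithmeticError):
    """A numerical routine left its domain of validity (e.g. non-PSD input)."""
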