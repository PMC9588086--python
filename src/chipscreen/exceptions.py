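"""Exception hierarchy shared across the package."""


class ChipscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ChipscreenError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedIndexError(ChipscreenError, ZeroDivisionError):
    """A ratio statistic is undefined (zero denominator), e.g. AMI at zero mean."""


class NoContrastError(ChipscreenError, ValueError):
    """The 100% and 0% reference channels have equal intensity."""


class FitError(ChipscreenError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics where available."""


class ConfigError(ChipscreenError, ValueError):
    """A pipeline or network configuration is malformed."""


class FormatError(ChipscreenError, ValueError):
    """A file is in an unsupported or malformed format."""


class PlacementError(ChipscreenError, RuntimeError):
    """Non-overlapping object placement failed within the retry budget."""
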