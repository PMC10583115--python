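"""Exception taxonomy shared across the package.

Every error raised by milslide derives from :class:`MilslideError`, so callers
can catch pipeline failures with a single except clause while still
distinguishing configuration mistakes from data problems.
"""


class MilslideError(Exception):
    """Base class for all milslide errors."""


class ConfigurationError(MilslideError):
    """Unknown backend/encoder/method name or inconsistent configuration."""


class ContractError(MilslideError):
    """An adapter does not implement the required abstract interface."""


class FormatError(MilslideError):
    """A file could not be read or does not match the expected schema."""


class BoundsError(MilslideError):
    """A region request falls outside the slide at the target level."""


class ShapeError(MilslideError):
    """Array dimensions inconsistent with model parameters."""


class ParameterError(MilslideError):
    """A numeric parameter is outside its valid range."""


class DegenerateInputError(MilslideError):
    """Input admits no meaningful answer (e.g. constant image, one class)."""


class NumericError(MilslideError):
    """Non-finite values were produced where finite ones are required."""


class StratificationError(MilslideError):
    """A label stratum is too small to split as requested."""


class UndefinedMetricError(MilslideError):
    """A metric is undefined for the given inputs (e.g. single-class AUROC)."""
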