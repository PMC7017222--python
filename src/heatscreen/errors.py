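"""Exception hierarchy shared by all heatscreen modules.

Every error raised on bad scientific input derives from :class:`HeatscreenError`
so that callers (and the CLI) can distinguish data problems from programming
bugs. Subclasses carry the failing field/column name in the message.
"""


class HeatscreenError(ValueError):
    """Base class for all domain errors raised by heatscreen."""


class DomainError(HeatscreenError):
    """An input value lies outside its physical or mathematical domain."""


class EmptyInputError(HeatscreenError):
    """An operation that requires at least one record received none."""


class DegenerateVarianceError(HeatscreenError):
    """A variance required to be positive is (numerically) zero."""


class DegenerateRangeError(HeatscreenError):
    """A min-max normalisation was attempted on constant values."""


class ShapeError(HeatscreenError):
    """Array dimensions are inconsistent with each other."""


class IncompleteRecordError(HeatscreenError):
    """A record is missing a required paired measurement."""


class ConfigError(HeatscreenError):
    """A simulation or pipeline configuration is invalid or infeasible."""
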