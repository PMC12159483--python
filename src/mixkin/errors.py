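"""Exception hierarchy.

Every error raised by the library derives from :class:`MixkinError` so callers
can catch the whole family; subclasses mirror the distinct failure modes
(bounds violations, rank deficiency, kinetic-transform domain errors, ...).
"""


class MixkinError(Exception):
    """Base class for all mixkin errors."""


class ValidationError(MixkinError, ValueError):
    """Input violates a structural invariant (e.g. proportions not summing to 1)."""


class BoundsError(ValidationError):
    """A mixture amount lies outside its component bounds or off the fixed total."""


class SizeError(ValidationError):
    """Too few observations/runs for the requested model."""


class SingularityError(MixkinError):
    """Design or regression matrix is rank deficient."""


class ConfigurationError(MixkinError, ValueError):
    """Unknown option value (model degree, goal kind, ...)."""


class ModelError(MixkinError, ValueError):
    """Model and evaluation point disagree (term count, component order)."""


class DomainError(MixkinError, ValueError):
    """Value outside the mathematical domain of a transform (log of <= 0, ...)."""


class DirectionError(MixkinError, ValueError):
    """A shelf-life limit is unreachable given the direction of change."""


class FeasibilityError(MixkinError, ValueError):
    """The constrained mixture region is empty or an optimization is infeasible."""


class ParseError(MixkinError, ValueError):
    """A CSV/config file does not match its schema."""
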