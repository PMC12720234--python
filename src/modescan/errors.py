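"""Exception hierarchy shared across the pipeline stages."""


class ModescanError(Exception):
    """Base class for all modescan errors."""


class ParseError(ModescanError):
    """A structured input file could not be parsed; the message names the line."""


class ShapeError(ModescanError):
    """Array dimensions inconsistent with the declared molecule size."""


class DegenerateModeError(ModescanError):
    """A normal-mode displacement vector has zero norm."""


class DomainError(ModescanError):
    """Input outside the mathematical domain of an operation."""


class LookupError_(ModescanError):
    """A requested mode or state is not present."""


class CompletenessError(ModescanError):
    """An energy table is missing grid points."""


class AmbiguityError(ModescanError):
    """An energy table contains duplicate (mode, i, state) records."""


class InsufficientDataError(ModescanError):
    """Too few points for the requested statistic."""


class DegenerateFitError(ModescanError):
    """Fewer than three distinct abscissa values for a quadratic fit."""


class UndefinedRatioError(ModescanError):
    """A normalized ratio has a zero denominator."""


class ElementTableError(ModescanError):
    """An element symbol is absent from the covalent-radius table."""


class NullProjectionError(ModescanError):
    """A mode vector projects to zero on every internal coordinate."""


class SpecError(ModescanError):
    """A synthetic-scenario specification is internally inconsistent."""
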