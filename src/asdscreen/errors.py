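"""Exception hierarchy shared across the screening stages.

The CLI maps these onto distinct exit codes (parse vs. domain vs.
degenerate-fit), so library code should raise the most specific class.
"""


class AsdScreenError(Exception):
    """Base class for all asdscreen errors."""


class ParseError(AsdScreenError):
    """Malformed input file or record; message names the offending row/field."""


class DomainError(AsdScreenError, ValueError):
    """Input outside the mathematical/physical domain of an operation."""


class ResolutionError(AsdScreenError, KeyError):
    """A structural-group label could not be resolved in the active table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class InsufficientDataError(AsdScreenError):
    """Too few points/profiles for the requested computation."""


class DegenerateFitError(AsdScreenError):
    """A regression problem with no usable solution (e.g. zero x-variance)."""


class SelectionError(AsdScreenError):
    """An atom/particle selection matched nothing."""


class StructuralError(AsdScreenError):
    """Inconsistent particle topology (e.g. hydrogen without a bonded donor)."""


class CapacityError(AsdScreenError):
    """A synthetic configuration cannot be packed under its constraints."""
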