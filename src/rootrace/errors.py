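"""Exception hierarchy for rootrace.

Exit-code mapping used by the CLI: usage errors -> 1, data/format errors -> 2,
numerical failures -> 3.
"""


class RootraceError(Exception):
    """Base class for all rootrace errors."""


class FormatError(RootraceError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(FormatError):
    """Volumetric data does not have exactly three axes."""


class ValidationError(RootraceError):
    """A domain object violates one of its invariants."""


class StructureError(RootraceError):
    """A root architecture file has an inconsistent tree structure."""


class EmptyForegroundError(RootraceError):
    """No voxel exceeds the minimum intensity threshold."""


class InfeasibleSpecError(RootraceError):
    """A synthesis specification cannot be realized (e.g. container too small)."""


class SolverError(RootraceError):
    """The hydraulic linear system could not be solved."""
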