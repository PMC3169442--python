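"""Exception hierarchy shared across the package."""


class ErvProfilerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ErvProfilerError, ValueError):
    """A file did not conform to the expected text format."""


class ParameterError(ErvProfilerError, ValueError):
    """A parameter violated an operation's contract."""


class DataError(ErvProfilerError, ValueError):
    """Input data are structurally valid but semantically unusable."""


class PlacementError(ErvProfilerError, RuntimeError):
    """Synthetic element copies could not be placed without overlap."""


class AlignmentError(ErvProfilerError, ValueError):
    """A clone could not be aligned end-gap-free to its reference."""


class StrandError(AlignmentError):
    """A bisulphite clone appears to come from the G->A converted strand."""


class DegenerateInputError(DataError):
    """The input is degenerate for the requested analysis (e.g. no CpG)."""


class UndefinedStatisticError(ErvProfilerError, ValueError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
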