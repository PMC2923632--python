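"""Exception hierarchy shared across the package."""


class SpacerHisError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(SpacerHisError):
    """Malformed FASTA input (names the offending line where possible)."""


class CoordinateError(SpacerHisError):
    """Feature interval outside its contig, or otherwise inconsistent."""


class FrameError(SpacerHisError):
    """CDS length not divisible by three."""


class ConsistencyError(SpacerHisError):
    """Cross-referenced inputs (proteome / CDS / family table) disagree."""


class ParameterError(SpacerHisError):
    """A search or alignment parameter violates its preconditions."""


class UndefinedValueError(SpacerHisError):
    """A statistic is requested where it is mathematically undefined."""


class ConfigError(SpacerHisError):
    """A synthetic-data configuration is internally contradictory."""
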