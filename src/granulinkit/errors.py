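"""Exception hierarchy for granulinkit."""


class GranulinError(Exception):
    """Base class for all granulinkit errors."""


class SequenceParseError(GranulinError):
    """Input sequence contains characters outside the accepted alphabet."""


class ConfigError(GranulinError):
    """Invalid configuration (empty spacing ranges, unknown keys, ...)."""


class CoordinateError(GranulinError):
    """Gene/protein coordinate systems do not agree."""


class ArchitectureParseError(GranulinError):
    """Exon token string contains symbols outside the supported grammar."""


class UnsupportedStructureError(GranulinError):
    """Gene structure cannot be expressed in the exon-token grammar."""


class AlignmentError(GranulinError):
    """Anchored alignment cannot be built from the given sequences."""


class DistanceError(GranulinError):
    """Distance undefined for the given pair (no comparable sites, ...)."""


class TreeError(GranulinError):
    """Tree operation failed (too few taxa, mismatched leaf sets, ...)."""
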