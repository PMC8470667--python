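"""Exception hierarchy shared by all analysis stages."""


class CypflexError(Exception):
    """Base class for all package errors."""


class ParseError(CypflexError):
    """A structure file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyStructureError(CypflexError):
    """No protein atoms remain after parsing or filtering."""


class TopologyError(CypflexError):
    """Coordinate data does not match the topology (e.g. atom-count mismatch)."""


class UnsupportedFormatError(CypflexError):
    """No adapter is registered for the requested trajectory format."""


class SelectionError(CypflexError):
    """A residue/atom selector resolved to nothing, or named a missing atom."""


class ConfigError(CypflexError):
    """Invalid run configuration (schema violation, malformed range, ...)."""


class AlignmentError(CypflexError):
    """Superposition is impossible (too few points, degenerate geometry)."""


class NotAlignedError(CypflexError):
    """An operation that assumes removed global motion got a raw trajectory."""


class PocketSeedError(CypflexError):
    """The contiguity seed point is excluded by a protein atom."""


class FitError(CypflexError):
    """An elastic-scan fit cannot be performed on the given window."""


class CorrelationError(CypflexError):
    """Pearson correlation undefined (constant input) or inputs mismatched."""
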