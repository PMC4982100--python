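"""Exception types shared across the package."""


class TraversalError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TraversalError, ValueError):
    """Malformed input file (PDB, trajectory log, fragment library)."""


class ValidationError(TraversalError, ValueError):
    """Structurally valid input that violates a documented invariant."""


class IncomparableStructuresError(TraversalError, ValueError):
    """Two structures/maps that cannot be compared (length or cutoff mismatch)."""


class DegenerateInputError(TraversalError, ValueError):
    """Input that makes the requested computation meaningless (e.g. all-zero
    distance matrix, all-zero weight matrix)."""


class DesignError(TraversalError, ValueError):
    """Block-design table that is not a complete replicated block design."""
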