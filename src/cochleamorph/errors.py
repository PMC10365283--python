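"""Exception hierarchy for the pipeline stages."""


class CochleamorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CochleamorphError, ValueError):
    """An argument value violates an operation's contract."""


class FormatError(CochleamorphError, ValueError):
    """A file cannot be read or written in a supported format."""


class GeometryError(CochleamorphError, ValueError):
    """Degenerate geometric input (collinear landmarks, on-axis points, shape mismatch)."""


class CoverageError(CochleamorphError, ValueError):
    """A mask covers too little of the sampled angular range to contour."""


class TopologyError(CochleamorphError, ValueError):
    """A mask or mesh does not have the topology an operation requires."""


class GenerationError(CochleamorphError, RuntimeError):
    """Phantom generation could not satisfy its target within its attempt budget."""


class DomainError(CochleamorphError, ValueError):
    """A numeric input lies outside the mathematical domain of an operation."""
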