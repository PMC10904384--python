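"""Exception hierarchy for the gammasfc pipeline.

Every error raised by the library derives from :class:`GammaSFCError`, so
callers can catch pipeline failures with a single except clause while the
specific subclasses keep failure modes distinguishable (bad file format vs.
degenerate input vs. out-of-range parameter).
"""


class GammaSFCError(Exception):
    """Base class for all gammasfc errors."""


class FormatError(GammaSFCError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(GammaSFCError):
    """Parsed data violates a structural invariant (shape, symmetry, range)."""


class ParameterError(GammaSFCError):
    """A parameter is outside its documented domain."""


class DensityError(GammaSFCError):
    """Functional matrix cannot be thresholded to the structural density."""

    def __init__(self, message: str, achievable_density: float | None = None):
        super().__init__(message)
        self.achievable_density = achievable_density


class DegenerateNodeError(GammaSFCError):
    """A node has a constant connectivity row; correlation distance is undefined."""


class DegenerateGraphError(GammaSFCError):
    """The graph carries no weight at all (all-zero matrix)."""


class EmptyGraphError(GammaSFCError):
    """Modularity is undefined on a graph without links."""


class UndefinedDiceError(GammaSFCError):
    """DICE similarity of two empty sets is undefined."""


class InsufficientDataError(GammaSFCError):
    """Too few observations for the requested statistic."""


class GeneMatchError(GammaSFCError):
    """A gene set matched no gene symbol in the expression matrix."""
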