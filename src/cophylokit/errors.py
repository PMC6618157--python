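"""Exception hierarchy for cophylokit.

All package-specific failures derive from :class:`CophyloError` so callers
can catch one base class at API boundaries (e.g. the CLI).
"""


class CophyloError(Exception):
    """Base class for all cophylokit errors."""


class NewickParseError(CophyloError):
    """Malformed Newick input; carries an approximate character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (near position {position})"
        super().__init__(message)


class TreeValidationError(CophyloError):
    """A tree violates a structural invariant (negative lengths, <2 tips ...)."""


class NormalizationError(CophyloError):
    """Branch-length normalization impossible (e.g. all-zero branches)."""


class LabelMismatchError(CophyloError):
    """Two trees passed to a label-requiring distance have different tip sets."""


class AssociationError(CophyloError):
    """Invalid host-pathogen association table (unknown tips, empty table)."""


class SimulationError(CophyloError):
    """Illegal simulator state transition."""


class NonTerminatingConfigurationError(SimulationError):
    """Root phase reached with more than one pathogen lineage but a zero
    duplication rate: the coalescent clock would never ring."""


class KernelError(CophyloError):
    """Invalid kernel configuration or non-binary input trees."""


class CurveError(CophyloError):
    """Response-curve post-processing failure (constant curve, no 0.5 crossing)."""


class SampleSizeError(CophyloError):
    """Too few observations after constraint filtering."""
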