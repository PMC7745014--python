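"""Exception hierarchy for the SBM pipeline.

Every stage raises a subclass of :class:`SBMError`, so callers can catch a
single type at the pipeline boundary while tests can assert on the specific
failure mode.
"""


class SBMError(Exception):
    """Base class for all errors raised by this package."""


class SimulationError(SBMError):
    """Synthetic cohort could not be generated under the requested geometry."""


class CohortConsistencyError(SBMError):
    """Subject volumes disagree in grid shape or affine, or a file is missing."""


class DegenerateMaskError(SBMError):
    """The analysis mask is empty."""


class DimensionMismatchError(SBMError):
    """Vector/matrix shapes do not agree with the mask or with each other."""


class InsufficientDataError(SBMError):
    """Too few subjects (or too small a group) for the requested computation."""


class RankError(SBMError):
    """Requested model order exceeds the numerical rank of the data."""


class DivergenceError(SBMError):
    """Infomax weights blew up; retry with a smaller learning rate."""


class StabilityError(SBMError):
    """Fewer than two ICA runs survived; no stability analysis possible."""


class DegenerateSourceError(SBMError):
    """A source or loading column has zero variance."""


class ConfigError(SBMError):
    """Run configuration is invalid; the message lists every problem found."""
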