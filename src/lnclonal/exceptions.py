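"""Exception hierarchy for the spatial clonality pipeline.

Every error raised by this package derives from :class:`LnClonalError`, so
callers can catch pipeline failures without masking programming errors.
"""


class LnClonalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LnClonalError, ValueError):
    """A configuration object or parameter combination is invalid."""


class InvalidParameterError(LnClonalError, ValueError):
    """A numeric parameter is outside its allowed range."""


class InvalidDomainError(LnClonalError, ValueError):
    """A domain polygon is degenerate, non-convex, or empty."""


class EmptyPatternError(LnClonalError, ValueError):
    """An operation received or would produce a pattern with no points."""


class InsufficientPointsError(LnClonalError, ValueError):
    """A statistic needs more points than the pattern contains."""


class DegenerateThresholdError(LnClonalError, ValueError):
    """Automatic thresholding is undefined (e.g. constant-intensity channel)."""


class DegenerateHullError(LnClonalError, ValueError):
    """A convex hull cannot be formed (fewer than 3 points, or collinear)."""


class DegenerateTessellationError(LnClonalError, ValueError):
    """A Voronoi tessellation cannot be formed (< 2 distinct sites)."""


class DuplicateConflictError(LnClonalError, ValueError):
    """Coincident points carry conflicting color marks."""


class InvalidMaskError(LnClonalError, ValueError):
    """A binary mask is empty or shape-incompatible."""


class DegenerateTestError(LnClonalError, ValueError):
    """A statistical test is undefined (e.g. zero-variance paired differences)."""


class InputError(LnClonalError, ValueError):
    """Mismatched or otherwise unusable user input."""
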