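"""Exception hierarchy for the analysis pipeline."""


class ConedriftError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInputError(ConedriftError):
    """Input too small or degenerate for the requested operation."""


class TessellationError(ConedriftError):
    """Voronoi tessellation failed (e.g. collinear-only input)."""


class OutOfDomainError(ConedriftError):
    """Requested evaluation point or lag lies outside the valid domain."""


class GapError(ConedriftError):
    """A video frame has no usable native-rate samples (signal dropout)."""


class CurationError(ConedriftError):
    """Trial cannot be analyzed (trace gap during stimulus, empty set, ...)."""


class ResolutionError(ConedriftError):
    """Stimulus too small to be rendered on the raster grid."""


class FitError(ConedriftError):
    """Psychometric fit failed to converge or data are degenerate."""


class BinningError(ConedriftError):
    """Pooled trials cannot be formed into enough representative bins."""


class ConfigError(ConedriftError):
    """Scenario or run configuration is inconsistent."""
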