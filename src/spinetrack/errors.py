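"""Exception hierarchy shared across the pipeline."""


class SpineTrackError(Exception):
    """Base class for all spinetrack errors."""


class LoadError(SpineTrackError):
    """A file could not be read or parsed."""


class ShapeError(SpineTrackError):
    """Inconsistent or invalid array dimensions."""


class ParameterError(SpineTrackError):
    """A parameter violates its documented contract."""


class DegenerateInputError(SpineTrackError):
    """Input carries no usable signal (e.g. a constant image)."""


class SegmentationError(SpineTrackError):
    """Segmentation failed to produce a usable mask."""


class AmbiguityError(SegmentationError):
    """Several equally plausible structures; caller must disambiguate."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class FitError(SpineTrackError):
    """A model fit failed or its result violates a sanity bound."""


class TracingError(SpineTrackError):
    """Geodesic path tracing stagnated before reaching the source."""


class NormalizationError(SpineTrackError):
    """A normalizer is zero or otherwise unusable."""


class ContractViolation(SpineTrackError):
    """An internal post-condition failed; indicates a pipeline bug upstream."""
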