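"""Exception hierarchy for the speedclimb pipeline.

All errors raised by the library derive from :class:`SpeedClimbError` so
callers (in particular the cohort pipeline, which must skip failing runs
rather than abort) can catch one base class.
"""


class SpeedClimbError(Exception):
    """Base class for all speedclimb errors."""


class ConfigurationError(SpeedClimbError):
    """Invalid configuration: bad model choice, weights, or generator params."""


class UnusableTrackError(SpeedClimbError):
    """Keypoint track has fewer than 2 valid frames; nothing to interpolate."""


class ResamplingRequiredError(SpeedClimbError):
    """Timestamps deviate from uniform sampling beyond tolerance."""


class HoldNotReachedError(SpeedClimbError):
    """COG never crosses the requested height in the upward direction."""


class IncompleteRunError(SpeedClimbError):
    """A required hold crossing is missing from the trace."""


class TruncatedRecordingError(SpeedClimbError):
    """Recording ends before downward body movement; ROI end undefined."""


class NoDecayError(SpeedClimbError):
    """No decreasing velocity phase inside the end-time ROI."""


class NoInflectionError(SpeedClimbError):
    """Second derivative of velocity has no sign change in the decay phase."""


class MetadataError(SpeedClimbError):
    """Inconsistent run metadata (e.g. non-positive tgt, tgt before t20)."""


class CannotAnchorError(SpeedClimbError):
    """No quasi-rest period at the start of the trace; t0 undefined."""


class WindowUndefinedError(SpeedClimbError):
    """Fewer than two velocity peaks; fit window cannot be selected."""


class UndefinedPhaseError(SpeedClimbError):
    """All-zero signal: analytic-signal phase is undefined."""


class NoSpectrumError(SpeedClimbError):
    """All-zero signal: no spectral content."""


class R2UndefinedError(SpeedClimbError):
    """SST is zero (constant data); R^2 is undefined."""


class FitFailureError(SpeedClimbError):
    """Optimizer failed to converge from every start; carries best effort."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class MetricUndefinedError(SpeedClimbError):
    """Peak-distance (or similar) metric has no peaks to match."""


class TooShortError(SpeedClimbError):
    """Series shorter than the zero-phase filter warm-up length."""


class UndefinedCorrelationError(SpeedClimbError):
    """Pearson correlation undefined for constant input."""


class SampleSizeError(SpeedClimbError):
    """Too few samples for the requested statistic (n < 3 for Pearson)."""


class EmptyInputError(SpeedClimbError):
    """Empty collection where at least one element is required."""
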