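"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`AdaptationError`, so callers (and the CLI) can distinguish
domain errors from programming errors.
"""


class AdaptationError(Exception):
    """Base class for all adaptrate errors."""


class DegenerateGainError(AdaptationError):
    """The estimated controller gain is too close to zero to plan a command."""


class UndefinedFusionError(AdaptationError):
    """Perceptual fusion is undefined (prior and sensory variance both zero
    while the cues disagree)."""


class UndefinedUpdateError(AdaptationError):
    """Parameter update is undefined (zero innovation variance)."""


class DegenerateVarianceError(AdaptationError):
    """The regression predictor has zero variance."""


class TooShortSeriesError(AdaptationError):
    """Fewer trials than the estimator's minimum (3 trials = 2 lagged pairs)."""


class NonContiguousSeriesError(AdaptationError):
    """Trial series contains gaps; estimators require contiguous trials."""


class MissingLatentError(AdaptationError):
    """An estimator needs a latent series (x_u, x_p or the per-trial control
    noise) that the input does not carry."""


class TooShortSegmentError(AdaptationError):
    """An empirical segment is shorter than the minimum analyzable length."""


class WindowOverflowError(AdaptationError):
    """A requested analysis window extends past the end of the simulation."""


class IncompleteMatrixError(AdaptationError):
    """The subject-by-condition matrix has missing cells."""


class SchemaError(AdaptationError):
    """An input table does not match the expected column schema."""
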