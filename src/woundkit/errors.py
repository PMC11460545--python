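"""Exception hierarchy shared across the toolkit.

Every error raised on bad caller input derives from :class:`InvalidInputError`
so the CLI can map it to a single exit code; failures of a pipeline *stage*
(segmentation found nothing, no fiducial in frame) derive from
:class:`StageFailure` and are recoverable where the pipeline allows it.
"""


class WoundkitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(WoundkitError, ValueError):
    """The caller supplied an argument that violates an operation's contract."""


class DegeneratePlaneError(InvalidInputError):
    """A constant grayscale plane cannot be thresholded."""


class StageFailure(WoundkitError):
    """A pipeline stage produced no usable result on an otherwise valid input."""


class SegmentationError(StageFailure):
    """Skin/background segmentation produced an empty foreground."""


class MarkerNotFoundError(StageFailure):
    """No fiducial marker could be detected in the image."""


class UndefinedMetricError(InvalidInputError):
    """A metric is undefined for the given inputs (e.g. AP with no ground truth)."""
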