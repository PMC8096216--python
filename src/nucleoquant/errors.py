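"""Exception hierarchy for nucleoquant.

All domain errors derive from :class:`NucleoQuantError` so batch drivers can
catch one base class, record the failure per image, and keep going.
"""


class NucleoQuantError(Exception):
    """Base class for all nucleoquant domain errors."""


class ImageFormatError(NucleoQuantError):
    """Input file is unreadable or structurally invalid (ragged pages, negatives)."""


class DegenerateImageError(NucleoQuantError):
    """Image carries no usable contrast (e.g. all intensities identical)."""


class EmptySignalError(NucleoQuantError):
    """Thresholding left no foreground voxels to measure."""


class GeometryError(NucleoQuantError):
    """A geometric precondition failed (shape mismatch, object does not fit)."""


class UndefinedStatisticError(NucleoQuantError):
    """The requested statistic is undefined for this input (zero variance, mu = 0)."""


class InsufficientDataError(NucleoQuantError):
    """Not enough records/pairs/voxels to evaluate the statistic."""
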