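"""Background thresholding of fluorescence stacks and projections.

A single Otsu threshold separates cellular background from nucleolar signal.
Voxels at or below the threshold are background (the strict ``intensity > t``
rule makes the tie behaviour deterministic); in exported "NaN views" they are
set to NaN so downstream statistics ignore them, mirroring how the original
analysis removed sub-threshold pixels.

The threshold is computed on the exact multiset of observed intensities:
candidate cut points are the distinct values and the maximizer of the
between-class variance is returned (first maximizer on ties).  This makes the
result exactly invariant under affine intensity rescaling and exactly
equivalent to an exhaustive intra-class-variance scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import DegenerateImageError, EmptySignalError
from .image_io import ProjectionImage, VoxelStack


def otsu_threshold(values) -> float:
    """Single-level Otsu threshold over a collection of intensities.

    Returns the value ``t`` (one of the observed distinct values) such that
    splitting into background ``<= t`` and foreground ``> t`` maximizes the
    between-class variance.  Requires at least two distinct finite values.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    levels, counts = np.unique(v, return_counts=True)
    if levels.size < 2:
        raise DegenerateImageError(
            "cannot threshold an image with fewer than 2 distinct intensities"
        )
    n = counts.sum()
    total = float((levels * counts).sum())
    # Cut after index i => background = levels[: i + 1]; skip the last cut
    # (empty foreground).
    w0 = np.cumsum(counts)[:-1].astype(np.float64)
    s0 = np.cumsum(levels * counts)[:-1]
    w1 = n - w0
    mu0 = s0 / w0
    mu1 = (total - s0) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(levels[int(np.argmax(between))])


@dataclass(frozen=True)
class FilteredStack:
    """A stack with its background threshold and foreground validity mask.

    Original intensities are retained; ``valid_mask`` is true exactly where
    ``intensity > threshold``.
    """

    source: VoxelStack
    threshold: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != self.source.intensities.shape:
            raise EmptySignalError("valid_mask shape does not match stack")
        object.__setattr__(self, "valid_mask", mask)

    @property
    def foreground_volume(self) -> int:
        """Number of voxels above the background threshold."""
        return int(self.valid_mask.sum())

    @property
    def foreground_values(self) -> np.ndarray:
        """Intensities of foreground voxels (1D)."""
        return self.source.intensities[self.valid_mask]

    def nan_view(self) -> np.ndarray:
        """Intensities with sub-threshold voxels replaced by NaN."""
        out = self.source.intensities.copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass(frozen=True)
class FilteredImage:
    """2D analogue of :class:`FilteredStack` for thresholded projections."""

    intensities: np.ndarray
    threshold: float
    valid_mask: np.ndarray

    @property
    def foreground_area(self) -> int:
        return int(self.valid_mask.sum())


def filter_stack(stack: VoxelStack, threshold: float | None = None) -> FilteredStack:
    """Threshold a stack (Otsu over all voxels unless ``threshold`` is given).

    Raises :class:`EmptySignalError` when no voxel exceeds the threshold and
    :class:`DegenerateImageError` for constant stacks (such crops indicate an
    upstream mistake rather than a measurable signal).
    """
    t = otsu_threshold(stack.intensities) if threshold is None else float(threshold)
    mask = stack.intensities > t
    if not mask.any():
        raise EmptySignalError(f"no voxels above threshold {t}")
    return FilteredStack(source=stack, threshold=t, valid_mask=mask)


def filter_projection(
    projection: ProjectionImage, threshold: float | None = None
) -> FilteredImage:
    """Threshold a 2D projection the same way :func:`filter_stack` does a stack."""
    t = (
        otsu_threshold(projection.intensities)
        if threshold is None
        else float(threshold)
    )
    mask = projection.intensities > t
    if not mask.any():
        raise EmptySignalError(f"no pixels above threshold {t}")
    return FilteredImage(intensities=projection.intensities, threshold=t, valid_mask=mask)


def write_mask(path, filtered: FilteredStack | FilteredImage) -> None:
    """Export a validity mask as an 8-bit TIFF (foreground 255, background 0)."""
    tifffile.imwrite(path, filtered.valid_mask.astype(np.uint8) * 255)
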