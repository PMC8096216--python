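"""Two-channel voxel correlation and relative positional variance.

These statistics characterize how one nucleolar component sits relative to
another: a voxelwise Pearson correlation over the union of the two
foregrounds (so exclusion zones -- one signal pushed out of the other's core
-- depress the statistic instead of being invisible to it), and the relative
positional variance (rpv)

    rpv = sigma^2 / mu

of the distances from every foreground voxel of channel A to the centre of
channel B's signal.  Voxels intermixed throughout a ball of radius R give
rpv ~ R/20 (for a uniform ball mu = 3R/4 and sigma^2 = 3R^2/80); voxels
arranged in a thin shell around the ball are nearly equidistant from its
centre and give rpv ~ 0.  rpv carries units of length and scales linearly
under isotropic spatial rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    EmptySignalError,
    GeometryError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .segmentation import FilteredStack


@dataclass(frozen=True)
class ChannelCorrelation:
    pearson_r: float
    p_value: float
    n_voxels: int
    support_rule: str


@dataclass(frozen=True)
class PositionalDispersion:
    """Distance distribution of channel-A voxels about channel B's centre."""

    center_b: tuple[float, float, float]
    distances: np.ndarray
    mu: float
    sigma2: float
    rpv: float
    units: str


def channel_correlation(
    a: FilteredStack, b: FilteredStack, support: str = "union"
) -> ChannelCorrelation:
    """Pearson correlation of raw voxel intensities across two channels.

    ``support`` selects which voxels enter: ``"union"`` (default; valid in at
    least one channel), ``"intersection"``, ``"a"`` or ``"b"``.  Raw
    intensities are used on the support -- thresholding only defines which
    voxels participate, not their values.
    """
    if a.source.intensities.shape != b.source.intensities.shape:
        raise GeometryError(
            f"channel shapes differ: {a.source.intensities.shape} vs "
            f"{b.source.intensities.shape}"
        )
    if support == "union":
        mask = a.valid_mask | b.valid_mask
    elif support == "intersection":
        mask = a.valid_mask & b.valid_mask
    elif support == "a":
        mask = a.valid_mask
    elif support == "b":
        mask = b.valid_mask
    else:
        raise ValueError(f"unknown support rule {support!r}")
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"support {support!r} holds {n} voxels (< 3)")
    x = a.source.intensities[mask]
    y = b.source.intensities[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("degenerate variance on correlation support")
    res = stats.pearsonr(x, y)
    return ChannelCorrelation(
        pearson_r=float(res.statistic),
        p_value=float(res.pvalue),
        n_voxels=n,
        support_rule=support,
    )


def signal_center(
    b: FilteredStack, weighted: bool = True, units: str = "voxel"
) -> tuple[float, float, float]:
    """Centre of a signal in (z, y, x) coordinates.

    Intensity-weighted centroid of the foreground by default (robust to
    threshold jitter); ``weighted=False`` gives the plain mask centroid.
    ``units="um"`` scales by the voxel size.
    """
    coords = np.argwhere(b.valid_mask).astype(np.float64)
    if coords.shape[0] == 0:
        raise EmptySignalError("cannot locate centre of empty signal")
    if weighted:
        w = b.foreground_values
        center = (coords * w[:, None]).sum(axis=0) / w.sum()
    else:
        center = coords.mean(axis=0)
    if units == "um":
        center = center * np.asarray(b.source.voxel_size)
    elif units != "voxel":
        raise ValueError(f"unknown units {units!r}")
    return tuple(float(c) for c in center)


def relative_positional_variance(
    a: FilteredStack,
    center_b: tuple[float, float, float],
    units: str = "um",
    weighted: bool = False,
    variance: str = "population",
) -> PositionalDispersion:
    """sigma^2 / mu of channel-A voxel distances to ``center_b``.

    Each foreground voxel of A counts once regardless of intensity (an
    intensity-weighted variant is available via ``weighted=True``).
    ``center_b`` is given in voxel coordinates; with ``units="um"`` both the
    voxel coordinates and the centre are converted to physical micrometres
    (the default, since axial steps are usually anisotropic), while
    ``units="voxel"`` keeps index units and agrees with the physical mode for
    isotropic voxels up to the scale factor.
    """
    coords = np.argwhere(a.valid_mask).astype(np.float64)
    if coords.shape[0] < 2:
        raise InsufficientDataError("rpv needs >= 2 foreground voxels")
    center = np.asarray(center_b, dtype=np.float64)
    if units == "um":
        scale = np.asarray(a.source.voxel_size)
        coords = coords * scale
        center = center * scale
    elif units != "voxel":
        raise ValueError(f"unknown units {units!r}")
    distances = np.linalg.norm(coords - center, axis=1)
    if weighted:
        w = a.foreground_values
        mu = float(np.average(distances, weights=w))
        sigma2 = float(np.average((distances - mu) ** 2, weights=w))
    else:
        mu = float(distances.mean())
        ddof = 0 if variance == "population" else 1
        sigma2 = float(np.var(distances, ddof=ddof))
    if mu == 0:
        raise UndefinedStatisticError("rpv undefined: mean distance is zero")
    return PositionalDispersion(
        center_b=tuple(float(c) for c in center),
        distances=distances,
        mu=mu,
        sigma2=sigma2,
        rpv=sigma2 / mu,
        units=units,
    )
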