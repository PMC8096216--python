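"""FRAP recovery curves and percent recovery.

An experiment is the triple (pre-bleach image, laser-spot image, timelapse).
The recovery region is the intersection of the Otsu foregrounds of the
pre-bleach and laser images; its mean in the pre-bleach image anchors the
normalization.  Imaging photobleaching is estimated as the least-squares
linear slope of a reference region's per-frame mean (by default the
non-bleached signal: pre-bleach foreground minus the recovery region, so
recovery itself never contaminates the estimate) and undone by a ratio
correction against the fitted linear trend -- equivalent to the additive
linear correction to first order, but amplitude-matched, so regions dimmer
than the reference are not over-corrected.

Two recovery summaries are reported:

* ``percent_recovery`` -- normalized final frame minus normalized first
  post-bleach frame (the conventional definition; equals m(1 - e^{-kT}) for
  an ideal fully bleached spot with mobile fraction m and rate k);
* ``unrecovered_fraction`` -- 1 minus the normalized final frame (pre-bleach
  level minus final level).

When over-correction pushes the normalized curve above the pre-bleach level
(negative unrecovered fraction), the applied correction is shrunk by 10% per
iteration (at most 100) until the final frame sits below the pre-bleach
level again; ``rate_adjusted`` and the iteration count record whether and
how far the loop ran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InsufficientDataError, UndefinedStatisticError
from .segmentation import otsu_threshold

#: Acquisition default: 50 frames spanning 30 s.
DEFAULT_N_FRAMES = 50
DEFAULT_DURATION_S = 30.0


@dataclass(frozen=True)
class FrapExperiment:
    """(pre-bleach, laser, timelapse) triple with shared lateral geometry."""

    prebleach: np.ndarray
    laser: np.ndarray
    timelapse: np.ndarray
    frame_time: float = DEFAULT_DURATION_S / (DEFAULT_N_FRAMES - 1)

    def __post_init__(self) -> None:
        pre = np.asarray(self.prebleach, dtype=np.float64)
        las = np.asarray(self.laser, dtype=np.float64)
        tl = np.asarray(self.timelapse, dtype=np.float64)
        if pre.ndim == 3 and pre.shape[0] == 1:
            pre = pre[0]
        if las.ndim == 3 and las.shape[0] == 1:
            las = las[0]
        if pre.ndim != 2 or las.ndim != 2 or tl.ndim != 3:
            raise GeometryError("expected 2D pre-bleach/laser images and a 3D timelapse")
        if pre.shape != las.shape or pre.shape != tl.shape[1:]:
            raise GeometryError("pre-bleach, laser and timelapse shapes differ")
        if tl.shape[0] < 2:
            raise InsufficientDataError("timelapse needs >= 2 frames")
        object.__setattr__(self, "prebleach", pre)
        object.__setattr__(self, "laser", las)
        object.__setattr__(self, "timelapse", tl)

    @property
    def n_frames(self) -> int:
        return self.timelapse.shape[0]


@dataclass(frozen=True)
class RecoveryCurve:
    recovery_region: np.ndarray
    prebleach_mean: float
    raw_means: np.ndarray
    bleach_rate: float
    rate_adjusted: bool
    n_adjust_iterations: int
    normalized: np.ndarray
    percent_recovery: float
    unrecovered_fraction: float


def recovery_region(
    prebleach: np.ndarray, laser: np.ndarray
) -> tuple[np.ndarray, float]:
    """Bleached region to monitor, and its pre-bleach mean intensity.

    Region = Otsu foreground of the pre-bleach image intersected with the
    Otsu foreground of the laser-spot image; empty intersection means the
    bleach missed the signal.
    """
    pre = np.asarray(prebleach, dtype=np.float64)
    las = np.asarray(laser, dtype=np.float64)
    pre_mask = pre > otsu_threshold(pre)
    spot_mask = las > otsu_threshold(las)
    region = pre_mask & spot_mask
    if not region.any():
        raise GeometryError("bleach spot does not overlap the signal")
    return region, float(pre[region].mean())


def bleach_rate(timelapse: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Least-squares slope (intensity per frame) of the mean-intensity series."""
    slope, _ = _linear_trend(timelapse, mask)
    return slope


def _linear_trend(
    timelapse: np.ndarray, mask: np.ndarray | None
) -> tuple[float, float]:
    tl = np.asarray(timelapse, dtype=np.float64)
    if tl.shape[0] < 2:
        raise InsufficientDataError("need >= 2 frames to fit a bleach rate")
    if mask is None:
        means = tl.mean(axis=(1, 2))
    else:
        means = tl[:, mask].mean(axis=1)
    idx = np.arange(tl.shape[0], dtype=np.float64)
    slope, intercept = np.polyfit(idx, means, 1)
    return float(slope), float(intercept)


def normalize_with_correction(
    exp: FrapExperiment,
    reference: str = "signal",
    max_iterations: int = 100,
    shrink: float = 0.9,
) -> RecoveryCurve:
    """Photobleach-corrected, normalized recovery curve for one experiment.

    ``reference`` selects where the bleach rate is estimated:
    ``"signal"`` (default) -- pre-bleach Otsu foreground minus the recovery
    region; ``"frame_excluding_region"``; or ``"frame"`` (whole frame).
    """
    region, pre_mean = recovery_region(exp.prebleach, exp.laser)
    if pre_mean <= 0:
        raise UndefinedStatisticError("pre-bleach region mean must be positive")
    raw = exp.timelapse[:, region].mean(axis=1)

    pre_mask = exp.prebleach > otsu_threshold(exp.prebleach)
    if reference == "signal":
        ref_mask = pre_mask & ~region
    elif reference == "frame_excluding_region":
        ref_mask = ~region
    elif reference == "frame":
        ref_mask = None
    else:
        raise ValueError(f"unknown bleach-rate reference {reference!r}")
    if ref_mask is not None and not ref_mask.any():
        ref_mask = None  # tiny fields: fall back to the whole frame

    slope, intercept = _linear_trend(exp.timelapse, ref_mask)

    idx = np.arange(exp.n_frames, dtype=np.float64)
    rate_adjusted = False
    n_iter = 0
    if slope < 0 and intercept > 0:
        trend = intercept + slope * idx
        trend = np.maximum(trend, 1e-12 * intercept)  # guard trend crossing zero
        boost = intercept / trend - 1.0  # fractional loss to restore, per frame
        gain = 1.0
        while True:
            corrected = raw * (1.0 + gain * boost)
            normalized = corrected / pre_mean
            if 1.0 - normalized[-1] > 0 or n_iter >= max_iterations:
                break
            gain *= shrink
            n_iter += 1
            rate_adjusted = True
    else:
        corrected = raw
        normalized = corrected / pre_mean

    return RecoveryCurve(
        recovery_region=region,
        prebleach_mean=pre_mean,
        raw_means=raw,
        bleach_rate=slope,
        rate_adjusted=rate_adjusted,
        n_adjust_iterations=n_iter,
        normalized=normalized,
        percent_recovery=float(normalized[-1] - normalized[0]),
        unrecovered_fraction=float(1.0 - normalized[-1]),
    )


def percent_recovery(curve: RecoveryCurve) -> float:
    """Normalized final frame minus normalized first post-bleach frame."""
    if curve.normalized.size < 2:
        raise InsufficientDataError("need >= 2 frames")
    return float(curve.normalized[-1] - curve.normalized[0])
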