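"""Ground-truthed synthetic fluorescence images for every pipeline stage.

Two condensate regimes are emulated, matching the physics the measurements
are designed to discriminate:

* **PPPS** (polymer-polymer phase separation): a fixed amount of fluorophore
  spread over several Gaussian puncta inside a nucleolar bounding ellipsoid.
  Raising ``crosslink_density`` pulls the puncta together and tightens each
  one while the **total integrated intensity is held constant** -- the
  compressible regime, where volume shrinks and concentration rises.
* **LLPS** (liquid-liquid phase separation): a uniform spherical droplet at
  **fixed concentration**; varying the droplet volume changes the amount but
  not the density -- the incompressible regime.

Two-channel geometries (a second signal intermixed through, or shelled
around, a reference droplet) and FRAP experiments (exponential recovery of
a mobile fraction inside a bleach spot, under global exponential imaging
bleach) complete the set.  All images pass through the same rendering path:
Gaussian PSF blur, additive background, then Gaussian (sigma proportional to
the signal amplitude) or Poisson noise.  Every generator is deterministic in
(model, seed) and returns a :class:`GroundTruth` carrying all parameters and
realized quantities, so tests never rely on hidden constants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .frap import DEFAULT_DURATION_S, DEFAULT_N_FRAMES, FrapExperiment
from .image_io import DEFAULT_VOXEL_SIZE, VoxelStack

#: Default stack geometry echoing the 55 x 55 pixel crop convention.
DEFAULT_SHAPE: tuple[int, int, int] = (11, 55, 55)

#: Deeper default for objects (droplets up to R ~ 10 voxels) that cannot fit
#: 11 planes with the required 2-voxel margin.
DEEP_SHAPE: tuple[int, int, int] = (27, 55, 55)


@dataclass(frozen=True)
class LLPSModel:
    """Uniform droplet at fixed concentration (incompressible regime).

    ``concentration_jitter`` is the cell-to-cell coefficient of variation of
    the droplet concentration (lognormal, mean-preserving in log space); it
    emulates expression variability across a population and is independent
    of droplet volume, so the regime's defining property -- expected
    concentration constant across volumes -- is preserved.
    """

    concentration: float = 100.0  # intensity per voxel inside the droplet
    droplet_volume: float = 1500.0  # voxels
    concentration_jitter: float = 0.15  # CV of per-cell concentration
    psf_sigma: float = 0.5  # voxels; residual blur after deconvolution
    background_level: float = 10.0
    noise_model: str = "gaussian"  # gaussian | poisson | none
    noise_level: float = 0.05  # sigma as fraction of signal amplitude
    seed: int = 0


@dataclass(frozen=True)
class PPPSModel:
    """Conserved-intensity multi-puncta condensate (compressible regime).

    ``crosslink_density`` in [0, 1] sets how tightly the puncta cluster and
    how sharp each punctum is; the integrated intensity is rescaled after
    placement so it is identical across densities.
    """

    total_integrated_intensity: float = 2.0e5
    n_puncta: int = 12
    crosslink_density: float = 0.5
    punctum_sigma_range: tuple[float, float] = (2.0, 0.9)  # voxels, density 0 -> 1
    cluster_radius_range: tuple[float, float] = (16.0, 5.0)  # voxels, density 0 -> 1
    psf_sigma: float = 0.5
    background_level: float = 10.0
    noise_model: str = "gaussian"
    noise_level: float = 0.05
    #: Intensity scale the Gaussian noise sigma is quoted against (detector
    #: noise does not grow as compaction concentrates the signal peak).
    noise_reference: float = 100.0
    seed: int = 0


@dataclass(frozen=True)
class TwoChannelModel:
    """Reference droplet (B) plus intermixed or shell companion signal (A)."""

    geometry: str = "intermixed"  # intermixed | shell
    radius: float = 10.0  # voxels
    shell_thickness: float = 1.5  # voxels
    intensity_a: float = 100.0
    intensity_b: float = 100.0
    psf_sigma: float = 0.8
    background_level: float = 10.0
    noise_model: str = "gaussian"
    noise_level: float = 0.02
    seed: int = 0


@dataclass(frozen=True)
class FrapModel:
    """Exponential recovery of a mobile fraction under linear-ish bleaching.

    Spot intensity follows
    ``I(t) = [I_post + m (I_pre - I_post)(1 - e^{-kt})] e^{-beta t}``;
    the surrounding signal bleaches as ``I_pre e^{-beta t}``.
    """

    mobile_fraction: float = 0.5
    recovery_rate: float = 0.3  # per second
    bleach_rate: float = 0.0  # imaging bleach, per second
    post_bleach_depth: float = 0.0  # I_post as a fraction of I_pre
    n_frames: int = DEFAULT_N_FRAMES
    duration: float = DEFAULT_DURATION_S  # seconds
    i_pre: float = 100.0
    signal_radius: float = 14.0  # pixels
    spot_radius: float = 4.0
    spot_offset: tuple[float, float] = (0.0, 5.0)  # (dy, dx) from centre
    frame_shape: tuple[int, int] = (55, 55)
    background_level: float = 0.0
    noise_model: str = "gaussian"
    noise_level: float = 0.02
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters plus realized quantities for one image."""

    params: dict = field(default_factory=dict)
    realized_volume: int = 0
    realized_integrated_intensity: float = 0.0
    center: tuple[float, ...] = ()


def _render(
    clean: np.ndarray,
    psf_sigma: float,
    background: float,
    noise_model: str,
    noise_level: float,
    rng: np.random.Generator,
    signal_amplitude: float,
) -> np.ndarray:
    img = clean
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=psf_sigma)
    img = img + background
    if noise_model == "gaussian" and noise_level > 0:
        img = img + rng.normal(0.0, noise_level * signal_amplitude, size=img.shape)
    elif noise_model == "poisson":
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    elif noise_model not in ("none", "gaussian"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    return np.maximum(img, 0.0)


def _ball_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=np.float64)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2


def generate_llps(
    model: LLPSModel,
    shape: tuple[int, int, int] = DEEP_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    rng: np.random.Generator | None = None,
) -> tuple[VoxelStack, GroundTruth]:
    """Uniform droplet of the requested volume at a random interior position."""
    rng = np.random.default_rng(model.seed) if rng is None else rng
    radius = (3.0 * model.droplet_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin = radius + 2.0
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=np.float64) - 1.0 - margin
    if np.any(hi < lo):
        raise GeometryError(
            f"droplet radius {radius:.1f} + 2-voxel margin does not fit shape {shape}"
        )
    center = rng.uniform(lo, hi)
    concentration = model.concentration
    if model.concentration_jitter > 0:
        concentration *= np.exp(rng.normal(0.0, model.concentration_jitter))
    mask = _ball_mask(shape, center, radius)
    clean = np.where(mask, concentration, 0.0)
    img = _render(
        clean,
        model.psf_sigma,
        model.background_level,
        model.noise_model,
        model.noise_level,
        rng,
        signal_amplitude=concentration,
    )
    truth = GroundTruth(
        params=asdict(model),
        realized_volume=int(mask.sum()),
        realized_integrated_intensity=float(clean.sum()),
        center=tuple(float(c) for c in center),
    )
    return VoxelStack(img, voxel_size=voxel_size, channel="llps"), truth


def generate_ppps(
    model: PPPSModel,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    rng: np.random.Generator | None = None,
) -> tuple[VoxelStack, GroundTruth]:
    """Multi-puncta condensate with conserved integrated intensity."""
    if model.n_puncta < 1:
        raise GeometryError("n_puncta must be >= 1")
    d = float(np.clip(model.crosslink_density, 0.0, 1.0))
    rng = np.random.default_rng(model.seed) if rng is None else rng
    s_lo_d, s_hi_d = model.punctum_sigma_range
    sigma_b = s_lo_d + d * (s_hi_d - s_lo_d)
    r_lo_d, r_hi_d = model.cluster_radius_range
    r_pos = r_lo_d + d * (r_hi_d - r_lo_d)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    # Puncta centres uniform in an ellipsoid: lateral semi-axis r_pos, axial
    # semi-axis capped so puncta stay inside the (shallower) z extent.
    z_semi = min(r_pos, max(center[0] - 2.0, 1.0))
    semi = np.array([z_semi, r_pos, r_pos])
    # rejection-sample the unit ball, scale per-axis
    offsets = []
    while len(offsets) < model.n_puncta:
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p**2).sum() <= 1.0:
            offsets.append(p * semi)
    zz, yy, xx = np.indices(shape, dtype=np.float64)
    clean = np.zeros(shape, dtype=np.float64)
    for off in offsets:
        cz, cy, cx = center + off
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        clean += np.exp(-0.5 * d2 / sigma_b**2)
    clean *= model.total_integrated_intensity / clean.sum()
    img = _render(
        clean,
        model.psf_sigma,
        model.background_level,
        model.noise_model,
        model.noise_level,
        rng,
        signal_amplitude=model.noise_reference,
    )
    truth = GroundTruth(
        params=asdict(model),
        realized_volume=int((clean > 0.01 * clean.max()).sum()),
        realized_integrated_intensity=float(clean.sum()),
        center=tuple(float(c) for c in center),
    )
    return VoxelStack(img, voxel_size=voxel_size, channel="ppps"), truth


def generate_two_channel(
    model: TwoChannelModel,
    shape: tuple[int, int, int] = DEEP_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    rng: np.random.Generator | None = None,
) -> tuple[VoxelStack, VoxelStack, GroundTruth]:
    """Reference droplet B and companion signal A sharing its centre.

    ``intermixed``: A uniformly fills B (fully mixed phases).  ``shell``: A
    occupies a spherical annulus of radial width ``shell_thickness`` centred
    on B's surface (the excluded configuration).
    """
    if model.radius < 4:
        raise GeometryError("droplet radius must be >= 4 voxels")
    if model.geometry == "shell" and model.shell_thickness >= model.radius:
        raise GeometryError("shell thickness must be < droplet radius")
    rng = np.random.default_rng(model.seed) if rng is None else rng
    outer = model.radius + (model.shell_thickness / 2 if model.geometry == "shell" else 0)
    if any(s < 2 * (outer + 2) + 1 for s in shape):
        raise GeometryError(f"radius {outer:.1f} + margin does not fit shape {shape}")
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    ball = _ball_mask(shape, center, model.radius)
    clean_b = np.where(ball, model.intensity_b, 0.0)
    if model.geometry == "intermixed":
        mask_a = ball
    elif model.geometry == "shell":
        mask_a = _ball_mask(
            shape, center, model.radius + model.shell_thickness / 2
        ) & ~_ball_mask(shape, center, model.radius - model.shell_thickness / 2)
    else:
        raise ValueError(f"unknown geometry {model.geometry!r}")
    clean_a = np.where(mask_a, model.intensity_a, 0.0)
    img_a = _render(
        clean_a, model.psf_sigma, model.background_level, model.noise_model,
        model.noise_level, rng, signal_amplitude=model.intensity_a,
    )
    img_b = _render(
        clean_b, model.psf_sigma, model.background_level, model.noise_model,
        model.noise_level, rng, signal_amplitude=model.intensity_b,
    )
    truth = GroundTruth(
        params=asdict(model),
        realized_volume=int(mask_a.sum()),
        realized_integrated_intensity=float(clean_a.sum()),
        center=tuple(float(c) for c in center),
    )
    stack_a = VoxelStack(img_a, voxel_size=voxel_size, channel="A")
    stack_b = VoxelStack(img_b, voxel_size=voxel_size, channel="B")
    return stack_a, stack_b, truth


def generate_frap(
    model: FrapModel,
    rng: np.random.Generator | None = None,
) -> tuple[FrapExperiment, GroundTruth]:
    """Render a FRAP triple (pre-bleach, laser-spot, timelapse).

    The spot sits inside a disc-shaped signal; the timelapse samples
    t_j = j * duration / (n_frames - 1).  The laser image marks the spot at
    twice the pre-bleach intensity so the spot mask is recoverable by the
    same Otsu rule the analysis applies.
    """
    if not 0.0 <= model.mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if model.recovery_rate < 0 or model.bleach_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(model.seed) if rng is None else rng
    h, w = model.frame_shape
    yy, xx = np.indices((h, w), dtype=np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    signal = (yy - cy) ** 2 + (xx - cx) ** 2 <= model.signal_radius**2
    sy, sx = cy + model.spot_offset[0], cx + model.spot_offset[1]
    spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= model.spot_radius**2
    if not (spot & signal).any():
        raise GeometryError("bleach spot lies outside the signal")

    def noisy(img: np.ndarray) -> np.ndarray:
        return _render(
            img, 0.0, model.background_level, model.noise_model,
            model.noise_level, rng, signal_amplitude=model.i_pre,
        )

    prebleach = noisy(np.where(signal, model.i_pre, 0.0))
    laser = noisy(np.where(spot, 2.0 * model.i_pre, 0.0))
    i_post = model.post_bleach_depth * model.i_pre
    t = np.arange(model.n_frames) * model.duration / (model.n_frames - 1)
    frames = np.empty((model.n_frames, h, w), dtype=np.float64)
    for j, tj in enumerate(t):
        decay = np.exp(-model.bleach_rate * tj)
        spot_val = (
            i_post
            + model.mobile_fraction * (model.i_pre - i_post)
            * (1.0 - np.exp(-model.recovery_rate * tj))
        ) * decay
        frame = np.where(signal, model.i_pre * decay, 0.0)
        frame[spot & signal] = spot_val
        frames[j] = noisy(frame)
    exp = FrapExperiment(
        prebleach=prebleach,
        laser=laser,
        timelapse=frames,
        frame_time=model.duration / (model.n_frames - 1),
    )
    expected = model.mobile_fraction * (1.0 - np.exp(-model.recovery_rate * model.duration))
    truth = GroundTruth(
        params=asdict(model),
        realized_volume=int((spot & signal).sum()),
        realized_integrated_intensity=float(prebleach.sum()),
        center=(float(sy), float(sx)),
    )
    truth.params["expected_percent_recovery"] = float(expected)
    return exp, truth
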