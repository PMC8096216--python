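"""Reading, writing and projecting fluorescence image stacks.

A :class:`VoxelStack` is the package's in-memory container for a cropped
z-stack (or a single-plane timelapse, with ``z`` reinterpreted as time and
``is_timelapse`` set).  Axis order is fixed as ``(z, y, x)``; TIFF pages map
to ``z``.  Integer pixel data are promoted to float64 once on ingest and all
downstream arithmetic is floating point.

The conventional crop used throughout is 55 x 55 pixels (3.5 x 3.5 um), but
arbitrary extents are accepted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import GeometryError, ImageFormatError

#: (dz, dy, dx) in micrometres for the standard crop: 55 px spanning 3.5 um
#: laterally; the axial step is acquisition-dependent and defaults to 300 nm.
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.3, 3.5 / 55.0, 3.5 / 55.0)

#: Sidecar metadata suffixes probed next to an image file.
_SIDECAR_SUFFIXES = (".yaml", ".yml")


@dataclass(frozen=True)
class VoxelStack:
    """A 3D fluorescence intensity array with voxel geometry.

    Parameters
    ----------
    intensities
        Non-negative finite array indexed ``(z, y, x)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres; all components strictly positive.
    channel
        Free-text channel label (e.g. ``"Cdc14-GFP"``).
    frame_time
        Seconds per frame for timelapses, else ``None``.
    is_timelapse
        When true, the leading axis is time rather than z.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""
    frame_time: float | None = None
    is_timelapse: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :]
        if arr.ndim != 3:
            raise ImageFormatError(f"expected a 2D or 3D array, got ndim={arr.ndim}")
        if arr.size == 0:
            raise ImageFormatError("empty image array")
        if not np.all(np.isfinite(arr)):
            raise ImageFormatError("intensities must be finite")
        if np.any(arr < 0):
            raise ImageFormatError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise GeometryError(f"voxel_size components must be > 0, got {vs}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D projection of a stack along z (``sum`` or ``max`` mode)."""

    intensities: np.ndarray
    mode: str
    source_depth: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ImageFormatError("projection must be 2D")
        object.__setattr__(self, "intensities", arr)


def project(stack: VoxelStack, mode: str = "sum") -> ProjectionImage:
    """Collapse a stack to a 2D image.

    ``sum`` mode: each pixel is the column sum over z (the convention used for
    homogeneity scoring).  ``max`` mode: the column maximum.
    """
    if mode == "sum":
        img = stack.intensities.sum(axis=0)
    elif mode == "max":
        img = stack.intensities.max(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}; expected 'sum' or 'max'")
    return ProjectionImage(intensities=img, mode=mode, source_depth=stack.n_planes)


def read_stack(
    path: str | Path,
    channel: str = "",
    voxel_size: tuple[float, float, float] | None = None,
    frame_time: float | None = None,
    is_timelapse: bool = False,
    use_sidecar: bool = True,
) -> VoxelStack:
    """Read a multi-page grayscale TIFF into a :class:`VoxelStack`.

    Pages must share dimensions; z equals the page count.  Pixel values are
    preserved bit-exactly as float64.  If a ``<name>.yaml`` sidecar sits next
    to the file it supplies defaults for voxel size, channel and frame time;
    explicit arguments win.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image file: {path}")
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ImageFormatError(f"failed to read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ImageFormatError(
            f"{path}: expected a grayscale stack, got shape {arr.shape}"
        )
    meta = _read_sidecar(path) if use_sidecar else {}
    if voxel_size is None:
        voxel_size = tuple(meta.get("voxel_size", DEFAULT_VOXEL_SIZE))
    if not channel:
        channel = str(meta.get("channel", ""))
    if frame_time is None:
        frame_time = meta.get("frame_time")
    return VoxelStack(
        intensities=arr.astype(np.float64),
        voxel_size=voxel_size,  # type: ignore[arg-type]
        channel=channel,
        frame_time=frame_time,
        is_timelapse=is_timelapse or bool(meta.get("is_timelapse", False)),
    )


def write_stack(path: str | Path, stack: VoxelStack, dtype: str = "float32") -> Path:
    """Write a stack as a multi-page TIFF (one page per plane)."""
    path = Path(path)
    data = stack.intensities
    if dtype.startswith(("uint", "int")):
        data = np.round(data).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def _read_sidecar(path: Path) -> dict:
    for suffix in _SIDECAR_SUFFIXES:
        candidate = path.with_suffix(suffix)
        if candidate.exists():
            with open(candidate) as fh:
                loaded = yaml.safe_load(fh)
            return loaded if isinstance(loaded, dict) else {}
    return {}


def center_crop(stack: VoxelStack, size: tuple[int, int] = (55, 55)) -> VoxelStack:
    """Crop the lateral extent to ``size`` about the image centre.

    A convenience for pre-cropped acquisition exports; interactive crop
    placement around a signal is an upstream step.
    """
    ny, nx = size
    _, h, w = stack.shape
    if ny > h or nx > w:
        raise GeometryError(f"crop {size} exceeds stack extent {(h, w)}")
    y0 = (h - ny) // 2
    x0 = (w - nx) // 2
    return replace(stack, intensities=stack.intensities[:, y0 : y0 + ny, x0 : x0 + nx])
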