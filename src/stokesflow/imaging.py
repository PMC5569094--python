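"""Calibrated image sequences and the low-level image operators.

Conventions
-----------
* Physical coordinates are ``(x, y[, z])`` in micrometres; pixel centres sit at
  ``(index + 0.5) * pixel_size`` along each axis.
* Arrays are stored in numpy index order: ``frame[row, col]`` in 2D (row <-> y,
  col <-> x) and ``frame[plane, row, col]`` in 3D (plane <-> z).
* Displacements and gradients are expressed in physical units (μm and
  intensity/μm respectively); conversion to pixels happens internally.
* Sampling outside the grid clamps to the nearest boundary value, so warping
  never injects artificial zeros at the cell edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

from .errors import FormatError

__all__ = [
    "ImageSequence",
    "load_sequence",
    "save_sequence",
    "gaussian_pyramid",
    "warp_image",
    "smoothed_gradient",
    "sample_at",
    "phys_to_index",
]


@dataclass
class ImageSequence:
    """Time-ordered stack of calibrated scalar frames (2D or 3D).

    Parameters
    ----------
    frames:
        List of float arrays, all of identical shape; ``(ny, nx)`` or
        ``(nz, ny, nx)``.
    pixel_size:
        Lateral calibration in μm per pixel (isotropic in-plane).
    dt:
        Frame interval in seconds.
    z_spacing:
        Axial plane spacing in μm (3D only).
    """

    frames: list[np.ndarray]
    pixel_size: float
    dt: float
    z_spacing: float | None = None

    def __post_init__(self):
        if len(self.frames) < 1:
            raise FormatError("sequence must contain at least one frame")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise FormatError(f"frame {i} shape {f.shape} != {shape}")
        if self.ndim == 3 and (self.z_spacing is None or self.z_spacing <= 0):
            raise ValueError("3D sequences require a positive z_spacing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def ndim(self) -> int:
        return self.frames[0].ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames[0].shape

    def spacings(self) -> np.ndarray:
        """Grid spacing per physical axis (x, y[, z]) in μm."""
        if self.ndim == 2:
            return np.array([self.pixel_size, self.pixel_size])
        return np.array([self.pixel_size, self.pixel_size, self.z_spacing])


def load_sequence(
    path,
    pixel_size: float,
    dt: float,
    z_spacing: float | None = None,
    n_planes: int | None = None,
) -> ImageSequence:
    """Load a multi-page TIFF as a calibrated sequence.

    3D+T acquisitions are stored T-major / Z-minor: page count must equal
    ``n_frames * n_planes``. Intensities are converted to float64 without
    rescaling.
    """
    if pixel_size <= 0 or dt <= 0:
        raise ValueError("calibration must be positive")
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:  # unreadable / truncated file
        raise OSError(f"cannot read TIFF {path!r}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.size == 0:
        raise FormatError(f"{path!r} contains no image data")
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"unsupported page layout with shape {pages.shape}")
    pages = pages.astype(np.float64)
    if n_planes is not None:
        if n_planes < 1 or pages.shape[0] % n_planes != 0:
            raise FormatError(
                f"page count {pages.shape[0]} is not a multiple of n_planes={n_planes}"
            )
        frames = [
            pages[i * n_planes : (i + 1) * n_planes]
            for i in range(pages.shape[0] // n_planes)
        ]
        return ImageSequence(frames, pixel_size, dt, z_spacing=z_spacing)
    return ImageSequence(list(pages), pixel_size, dt, z_spacing=z_spacing)


def save_sequence(path, seq: ImageSequence) -> None:
    """Write frames as a multi-page float32 TIFF (T-major, Z-minor in 3D)."""
    if seq.ndim == 2:
        stack = np.stack(seq.frames)
    else:
        stack = np.concatenate(seq.frames, axis=0)
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")


# σ chosen as 0.8·factor for anti-aliasing before subsampling
_PYRAMID_SIGMA_PER_FACTOR = 0.8
_MIN_LEVEL_SIZE = 8


def gaussian_pyramid(frame: np.ndarray, n_levels: int, factor: int = 2) -> list[np.ndarray]:
    """Multi-scale pyramid; ``levels[0]`` is the input (finest), higher indices
    are coarser (Gaussian smoothing by ``0.8*factor`` then subsampling).
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if min(frame.shape) // factor ** (n_levels - 1) < _MIN_LEVEL_SIZE:
        raise ValueError(
            f"{n_levels} levels would shrink shape {frame.shape} below "
            f"{_MIN_LEVEL_SIZE} px per axis"
        )
    levels = [np.asarray(frame, dtype=np.float64)]
    for _ in range(n_levels - 1):
        sm = ndimage.gaussian_filter(levels[-1], _PYRAMID_SIGMA_PER_FACTOR * factor)
        levels.append(sm[tuple(slice(None, None, factor) for _ in range(frame.ndim))])
    return levels


def phys_to_index(points: np.ndarray, pixel_size: float, z_spacing: float | None = None) -> np.ndarray:
    """Map physical (x, y[, z]) μm coordinates to fractional array indices.

    Returns index coordinates in array-axis order (row, col) or
    (plane, row, col), suitable for ``ndimage.map_coordinates``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = pts.shape[1]
    if d == 2:
        return np.stack([pts[:, 1] / pixel_size - 0.5, pts[:, 0] / pixel_size - 0.5])
    return np.stack(
        [
            pts[:, 2] / z_spacing - 0.5,
            pts[:, 1] / pixel_size - 0.5,
            pts[:, 0] / pixel_size - 0.5,
        ]
    )


def sample_at(
    frame: np.ndarray,
    points: np.ndarray,
    pixel_size: float,
    z_spacing: float | None = None,
    order: int = 1,
) -> np.ndarray:
    """Sample a grid at physical points by interpolation (clamped at edges)."""
    idx = phys_to_index(points, pixel_size, z_spacing)
    return ndimage.map_coordinates(
        np.asarray(frame, dtype=np.float64), idx, order=order, mode="nearest"
    )


def warp_image(
    frame: np.ndarray,
    disp: np.ndarray,
    pixel_size: float,
    z_spacing: float | None = None,
) -> np.ndarray:
    """Backward warp: ``output(x) = frame(x + disp(x))``.

    ``disp`` has shape ``(d, *frame.shape)`` with components in (x, y[, z])
    order and μm units. Linear interpolation; out-of-grid samples take the
    nearest boundary value.
    """
    frame = np.asarray(frame, dtype=np.float64)
    disp = np.asarray(disp, dtype=np.float64)
    if disp.shape != (frame.ndim,) + frame.shape:
        raise ValueError(
            f"displacement shape {disp.shape} does not match frame {frame.shape}"
        )
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in frame.shape], indexing="ij")
    if frame.ndim == 2:
        coords = [
            grids[0] + disp[1] / pixel_size,  # rows move by the y-component
            grids[1] + disp[0] / pixel_size,
        ]
    else:
        coords = [
            grids[0] + disp[2] / z_spacing,
            grids[1] + disp[1] / pixel_size,
            grids[2] + disp[0] / pixel_size,
        ]
    return ndimage.map_coordinates(frame, coords, order=1, mode="nearest")


def smoothed_gradient(
    frame: np.ndarray,
    sigma: float,
    pixel_size: float,
    z_spacing: float | None = None,
) -> np.ndarray:
    """Gaussian-smoothed central-difference gradient in intensity per μm.

    Returns an array of shape ``(d, *frame.shape)`` with components ordered
    (x, y[, z]).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    frame = np.asarray(frame, dtype=np.float64)
    sm = ndimage.gaussian_filter(frame, sigma) if sigma > 0 else frame
    if frame.ndim == 2:
        gy, gx = np.gradient(sm, pixel_size, pixel_size)
        return np.stack([gx, gy])
    gz, gy, gx = np.gradient(sm, z_spacing, pixel_size, pixel_size)
    return np.stack([gx, gy, gz])
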