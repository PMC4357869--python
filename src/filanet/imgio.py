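"""Image I/O, intensity normalization and isotropic resampling.

All downstream geometry (snakes, junctions, metrics) lives in isotropic
voxel units: 0-based coordinates, voxel centers at integer positions, axis
order (x, y, z).  A 2D image is treated as a 3D volume with z-extent 1.
Intensities are rescaled so that the image maximum equals 1 before
extraction; extraction parameters such as the ridge threshold are expressed
in these rescaled units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input image does not match the supported format."""


class DegenerateInputError(ValueError):
    """Raised for inputs that are valid in form but carry no usable signal."""


@dataclass
class Volume:
    """A scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity grid, axis order (x, y, z).  Float internally.
    spacing : tuple of float
        Physical voxel size along (x, y, z) in micrometres.
    rescaled : bool
        True once max-normalization has been applied (max intensity = 1).
    snr_hint : float or None
        Optional mean local SNR annotation (e.g. from a phantom).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rescaled: bool = False
    snr_hint: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise FormatError(f"expected 2D or 3D data, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_2d(self) -> bool:
        return self.data.shape[2] == 1

    def interp(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at fractional (x, y, z) coordinates.

        Points outside the grid evaluate to 0.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return ndimage.map_coordinates(
            self.data, pts.T, order=1, mode="constant", cval=0.0
        )

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel intensity reads (0 outside the grid).

        Used for background *statistics*: trilinear interpolation averages
        neighboring voxels and would bias the sample standard deviation low.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = np.round(pts).astype(int)
        shape = np.asarray(self.data.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts))
        ii = idx[inside]
        out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def load_stack(path, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Read a single- or multi-page grayscale TIFF into a Volume.

    Page order maps to increasing z.  2D input yields z-extent 1.  RGB or
    multi-sample images and stacks with non-uniform page sizes are rejected.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            page0 = tf.pages[0]
            if page0.samplesperpixel != 1:
                raise FormatError(
                    f"expected single-channel grayscale TIFF, got "
                    f"{page0.samplesperpixel} samples per pixel"
                )
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise FormatError(f"non-uniform page sizes: {sorted(shapes)}")
            arr = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"unreadable TIFF file {path!r}: {exc}") from exc
    if arr.ndim == 2:
        data = arr.T[:, :, None]  # (y, x) -> (x, y, 1)
    elif arr.ndim == 3:
        data = np.transpose(arr, (2, 1, 0))  # (z, y, x) -> (x, y, z)
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.shape}")
    return Volume(np.ascontiguousarray(data, dtype=np.float64), spacing=spacing)


def save_stack(v: Volume, path) -> None:
    """Write a Volume as a multi-page float32 TIFF (pages along z)."""
    arr = np.transpose(v.data, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


def subtract_background(v: Volume, offset: float) -> Volume:
    """Subtract a constant background offset and clamp at 0."""
    return replace(v, data=np.clip(v.data - offset, 0.0, None), rescaled=False)


def rescale(v: Volume) -> Volume:
    """Max-normalize intensity so that the volume maximum is exactly 1.

    Idempotent; all-zero input is rejected.
    """
    if v.rescaled:
        return v
    m = float(v.data.max())
    if m <= 0:
        raise DegenerateInputError("cannot rescale an all-zero volume")
    data = np.clip(v.data / m, 0.0, 1.0)  # x/x == 1.0 exactly in IEEE
    return replace(v, data=data, rescaled=True)


def resample_isotropic(v: Volume) -> Volume:
    """Resample onto an isotropic grid with spacing min(spacing) per axis.

    Trilinear interpolation; new extent along axis k is
    ceil(n_k * spacing_k / min(spacing)).  No-op when already isotropic.
    """
    target = min(v.spacing)
    if all(abs(s - target) < 1e-12 for s in v.spacing):
        return v
    new_shape = tuple(
        int(np.ceil(n * s / target)) for n, s in zip(v.data.shape, v.spacing)
    )
    grids = [
        np.arange(m, dtype=np.float64) * target / s
        for m, s in zip(new_shape, v.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    data = ndimage.map_coordinates(
        v.data, np.stack([c.ravel() for c in coords]), order=1, mode="nearest"
    ).reshape(new_shape)
    return replace(v, data=data, spacing=(target, target, target))
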