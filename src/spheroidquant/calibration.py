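"""Pixel calibration and the calibrated image-stack container.

All physical quantities in this package are micrometres (µm) or µm²; all
pixel coordinates are 0-based ``(row, col)`` with pixel centers at integer
coordinates. Slice 0 is the shallowest plane (closest to the objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of the voxel grid.

    Parameters
    ----------
    xy_size : float
        In-plane pixel size in µm per pixel (isotropic).
    z_step : float
        Distance between consecutive z-slices in µm.
    """

    xy_size: float
    z_step: float

    def __post_init__(self) -> None:
        if not (self.xy_size > 0 and self.z_step > 0):
            raise ValueError(
                f"calibration must be positive, got xy_size={self.xy_size}, "
                f"z_step={self.z_step}"
            )

    def area_um2(self, n_pixels: float) -> float:
        """Convert a pixel count to an area in µm² (factor xy_size²)."""
        return float(n_pixels) * self.xy_size**2

    def length_um(self, n_pixels: float) -> float:
        return float(n_pixels) * self.xy_size


@dataclass
class ImageStack:
    """A calibrated 3D intensity volume indexed ``(slice, row, col)``.

    ``depth_offset`` is the imaging depth (µm) of slice 0 below the upper
    specimen border; the depth of slice *i* is
    ``depth_offset + i * calibration.z_step``.
    """

    voxels: np.ndarray
    calibration: PixelCalibration
    depth_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[None, :, :]
        if v.ndim != 3:
            raise ValueError(f"stack must be 3D (slice,row,col), got ndim={v.ndim}")
        if v.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if not np.all(np.isfinite(v)):
            raise ValueError("stack intensities must be finite")
        if v.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice_depth(self, index: int) -> float:
        """Imaging depth (µm) of the given slice below the specimen border."""
        return self.depth_offset + index * self.calibration.z_step
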