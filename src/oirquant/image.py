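"""Calibrated raster containers.

An :class:`Image2D` is a single-channel 8- or 16-bit fluorescence image with
an optional spatial calibration in micrometres per pixel; a :class:`Stack3D`
is an ordered pile of equally shaped slices with voxel dimensions, the
substrate for lesion volumetry. Pixel coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["Image2D", "Stack3D"]


@dataclass(frozen=True)
class Image2D:
    """A single-channel intensity image.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Integer intensities in ``[0, 2**bit_depth - 1]``.
    bit_depth : {8, 16}
        Native bit depth of the acquisition.
    um_per_px : float, optional
        Micrometres per pixel (isotropic). ``None`` means uncalibrated;
        area reports then carry pixel counts only.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("Image2D requires a non-empty 2D array")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > (1 << self.bit_depth) - 1:
            raise FormatError(
                f"intensities outside [0, {(1 << self.bit_depth) - 1}] "
                f"for bit_depth={self.bit_depth}"
            )
        if self.um_per_px is not None and not self.um_per_px > 0:
            raise FormatError("um_per_px must be strictly positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_gray(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class Stack3D:
    """An ordered z-stack of equally shaped slices.

    ``dz`` defaults to 1.5 μm, the serial-section interval used when
    z-stacks span the full depth of a laser-induced CNV lesion.
    """

    slices: np.ndarray  # (nz, rows, cols)
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.5
    bit_depth: int = 8

    def __post_init__(self) -> None:
        vol = np.asarray(self.slices)
        if vol.ndim != 3 or vol.shape[0] < 1:
            raise FormatError("Stack3D requires a (nz, rows, cols) array with nz >= 1")
        for name, v in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not v > 0:
                raise FormatError(f"{name} must be strictly positive")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        object.__setattr__(self, "slices", vol)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz
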