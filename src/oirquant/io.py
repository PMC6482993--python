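"""Image and report I/O.

TIFF (single and multi-page, 8/16-bit) via tifffile, PNG (8-bit) via
imageio. Multi-channel input requires an explicit channel index. Masks are
serialized as 0/255 8-bit TIFF pages; reports as CSV with a deterministic
column order, percentages at 4 decimal places and the package version
recorded per row, so re-running an analysis reproduces the file byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import FormatError
from .image import Image2D, Stack3D

__all__ = ["read_image", "write_image", "write_masks_tiff", "write_report", "RunConfig"]

REPORT_FLOAT_FMT = "%.4f"


def _to_image2d(arr: np.ndarray, channel: int | None, um_per_px: float | None) -> Image2D:
    if arr.ndim == 3:
        if channel is None:
            if arr.shape[-1] in (3, 4):
                raise FormatError(
                    "multi-channel image: pass a channel index (e.g. --channel 0)"
                )
            raise FormatError("3D array where a 2D image was expected")
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"unsupported dtype {arr.dtype}; need uint8 or uint16")
    return Image2D(arr, bit_depth=depth, um_per_px=um_per_px)


def read_image(
    path: str | Path,
    channel: int | None = None,
    um_per_px: float | None = None,
    dz: float = 1.5,
) -> Image2D | Stack3D:
    """Read a TIFF/PNG; multi-page TIFF returns a :class:`Stack3D`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
            if arr.dtype not in (np.uint8, np.uint16):
                raise FormatError(f"unsupported dtype {arr.dtype}")
            depth = 8 if arr.dtype == np.uint8 else 16
            cal = um_per_px if um_per_px else 1.0
            return Stack3D(arr, dx=cal, dy=cal, dz=dz, bit_depth=depth)
        return _to_image2d(arr, channel, um_per_px)
    if suffix == ".png":
        return _to_image2d(np.asarray(iio.imread(path)), channel, um_per_px)
    raise FormatError(f"unsupported format {suffix!r}; use TIFF or PNG")


def write_image(path: str | Path, image: Image2D | Stack3D | np.ndarray) -> None:
    if isinstance(image, Image2D):
        arr = image.pixels
    elif isinstance(image, Stack3D):
        arr = image.slices
    else:
        arr = np.asarray(image)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        # 3/4-page stacks must not be mistaken for RGB component planes
        tifffile.imwrite(path, arr, photometric="minisblack")
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported output format {path.suffix!r}")


def write_masks_tiff(path: str | Path, masks: list[np.ndarray]) -> None:
    """Write binary masks as a multi-page 0/255 8-bit TIFF."""
    pages = np.stack([np.where(np.asarray(m, dtype=bool), 255, 0).astype(np.uint8) for m in masks])
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def write_report(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Deterministic CSV report: fixed column order, 4-decimal floats."""
    for r in rows:
        r.setdefault("oirquant_version", __version__)
    if columns is None:
        columns = sorted({k for r in rows for k in r}) if rows else []
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    df.to_csv(Path(path), index=False, float_format=REPORT_FLOAT_FMT)


@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration (subcommand parameters + seed)."""

    subcommand: str = ""
    parameters: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    verbosity: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
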