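"""Radiograph I/O, background estimation and Lambert-Beer normalization.

The background intensity ``I0`` is the histogram mode of the integer grey
values: the sample holder leaves most of the detector uncovered, so the
most frequent grey value is the unattenuated background.  Normalization is
the element-wise attenuation transform ``-ln(I / I0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "Radiograph",
    "AttenuationImage",
    "estimate_background",
    "normalize",
    "read_radiograph",
    "write_radiograph",
    "write_attenuation",
]


@dataclass(frozen=True)
class Radiograph:
    """Raw detector image (integer counts) plus acquisition metadata."""

    pixels: np.ndarray
    pixel_size_um: float = 49.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        if np.min(px) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class AttenuationImage:
    """Unitless attenuation line integrals, -ln(I/I0)."""

    values: np.ndarray
    background_I0: int


def estimate_background(image: Radiograph) -> int:
    """Mode of the integer grey-value histogram.

    Float inputs are rounded to the nearest integer grey level first.
    Ties are broken toward the largest grey value (in transmission imaging
    the dominant bright region is the uncovered background).
    """
    counts = np.rint(np.asarray(image.pixels)).astype(np.int64).ravel()
    if np.all(counts == 0):
        raise ValueError("all-zero image: background intensity undefined")
    hist = np.bincount(counts)
    best = hist.max()
    mode = int(np.flatnonzero(hist == best)[-1])
    return mode


def normalize(image: Radiograph, i0: Union[int, str] = "auto") -> AttenuationImage:
    """Apply ``I_corr = -ln(I / I0)`` element-wise.

    ``i0='auto'`` estimates the background from the histogram mode.
    Zero counts are floored to one count before the log to avoid
    infinities; counts above I0 produce small negative values which are
    kept (not clipped) to preserve noise statistics.
    """
    if isinstance(i0, str):
        if i0 != "auto":
            raise ValueError("i0 must be an integer or 'auto'")
        i0_val = estimate_background(image)
    else:
        i0_val = int(i0)
    if i0_val <= 0:
        raise ValueError("I0 must be > 0")
    counts = np.maximum(np.asarray(image.pixels, dtype=np.float64), 1.0)
    values = -np.log(counts / i0_val)
    return AttenuationImage(values=values, background_I0=i0_val)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_radiograph(path: Union[str, Path], pixel_size_um: float = 49.5) -> Radiograph:
    """Read an 8/16-bit single-channel TIFF or PNG radiograph."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {data.shape}")
    return Radiograph(pixels=data.astype(np.uint16), pixel_size_um=pixel_size_um)


def write_radiograph(path: Union[str, Path], pixels: np.ndarray) -> None:
    """Write detector counts as 16-bit TIFF (or PNG preview)."""
    path = Path(path)
    data = np.asarray(pixels, dtype=np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_attenuation(path: Union[str, Path], att: AttenuationImage) -> None:
    """Write the attenuation image as 32-bit float TIFF."""
    tifffile.imwrite(
        Path(path),
        att.values.astype(np.float32),
        metadata={"background_I0": att.background_I0},
    )
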