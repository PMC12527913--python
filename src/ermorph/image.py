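"""Calibrated 2D images and TIFF round-tripping."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import tifffile

MASK_BACKGROUND = 0
MASK_TUBULE = 1
MASK_SHEET = 2
MASK_CLASS_NAMES = {MASK_BACKGROUND: "background",
                    MASK_TUBULE: "tubule",
                    MASK_SHEET: "sheet"}


@dataclass
class Image:
    """2D fluorescence intensity image with a physical pixel size (um/px)."""

    data: np.ndarray
    pixel_size: float
    channel: str = ""
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.data, dtype=float)
        if a.ndim != 2:
            raise ValueError("image must be 2D")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("intensities must be finite and >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.data = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def write_tiff(path, img: Image) -> None:
    res = 1.0 / img.pixel_size
    tifffile.imwrite(path, img.data.astype(np.float32),
                     resolution=(res, res),
                     metadata={"unit": "um", "channel": img.channel})


def read_tiff(path, pixel_size: Optional[float] = None, channel: str = "") -> Image:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        if pixel_size is None:
            page = tf.pages[0]
            try:
                xr = page.tags["XResolution"].value
                pixel_size = xr[1] / xr[0]
            except (KeyError, ZeroDivisionError):
                raise ValueError("no pixel size in TIFF; pass pixel_size")
    return Image(data=data, pixel_size=float(pixel_size), channel=channel)


def write_mask(path, mask: np.ndarray, pixel_size: float) -> None:
    """8-bit class mask TIFF, palette {0 background, 1 tubule, 2 sheet}."""
    m = np.asarray(mask)
    if not np.isin(m, [MASK_BACKGROUND, MASK_TUBULE, MASK_SHEET]).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    res = 1.0 / pixel_size
    tifffile.imwrite(path, m.astype(np.uint8), resolution=(res, res),
                     metadata={"unit": "um"})


def read_mask(path) -> np.ndarray:
    m = tifffile.imread(path)
    if not np.isin(m, [MASK_BACKGROUND, MASK_TUBULE, MASK_SHEET]).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    return m.astype(np.uint8)
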