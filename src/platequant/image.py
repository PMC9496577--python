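"""The in-memory RGB raster container shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass
class PlateImage:
    """An RGB raster with a validity mask and provenance metadata.

    ``data`` is an (H, W, 3) array, either uint8 straight from a camera /
    PNG or float64 after alignment and flat-field correction (values on
    the 0-255 scale).  ``mask`` marks valid pixels; pixels that fall
    outside the source frame after warping are masked out and excluded
    from every downstream histogram.  ``scale_px_per_mm`` is set once the
    image lives in the canonical plate frame.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    provenance: str = "test"
    scale_px_per_mm: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[2] != 3:
            raise ValueError("plate image must be an (H, W, 3) RGB array")
        self.data = data
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValueError("mask shape must match the image frame")
            self.mask = mask

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return self.mask

    def to_float(self) -> np.ndarray:
        return np.asarray(self.data, dtype=np.float64)

    def write_png(self, path: str | Path) -> None:
        """Write as 8-bit PNG (half-even rounding for float data)."""
        arr = self.data
        if arr.dtype != np.uint8:
            arr = np.round(np.clip(arr, 0, 255)).astype(np.uint8)
        iio.imwrite(Path(path), arr, extension=".png")

    @classmethod
    def read_png(cls, path: str | Path, provenance: str = "test") -> "PlateImage":
        arr = iio.imread(Path(path))
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        return cls(data=arr.astype(np.uint8), provenance=provenance)
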