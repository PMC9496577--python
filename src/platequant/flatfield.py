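"""Flat-field calibration from a white-block image.

Illumination is never homogeneous across the plate: the four corner LEDs
leave a centre-to-edge gradient and the sensor adds its own spatial
response.  A white-block image taken under the same optics captures that
field; dividing it out makes the concentration measurement invariant to
illumination changes.  The correction is purely multiplicative — a
single well-exposed white exposure carries no dark-frame information, so
the dark offset is taken as negligible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import CalibrationError
from .image import PlateImage

#: Gaussian smoothing of the white image before division, as a fraction of
#: image width: suppresses target texture and sensor noise while leaving
#: the (much smoother) illumination field intact.
DEFAULT_SIGMA_FRAC = 0.02
#: Channel saturation threshold on the 8-bit scale.
SATURATION_LEVEL = 254.5
#: Largest tolerated fraction of saturated pixels per channel.
MAX_SATURATED_FRAC = 0.01
#: Gain maps with a larger max/min ratio indicate a broken white exposure.
MAX_GAIN_RATIO = 10.0


@dataclass
class FlatField:
    """Per-pixel, per-channel multiplicative gain map.

    ``gain[p, ch] = reference[ch] / white_smoothed[p, ch]`` where the
    reference level is the channel-wise median of the smoothed white
    image.  ``mask`` marks pixels where the white image was valid.
    """

    gain: np.ndarray  # (H, W, 3)
    reference: np.ndarray  # (3,) channel reference levels
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise CalibrationError("gain map must be (H, W, 3)")
        valid = self.gain[self.mask]
        if valid.size and (not np.all(np.isfinite(valid)) or valid.min() <= 0):
            raise CalibrationError("gains must be strictly positive and finite")

    def save(self, tiff_path: str | Path, json_path: str | Path) -> None:
        """Serialise as a 16-bit TIFF gain map plus JSON metadata."""
        scale = 65535.0 / float(self.gain.max())
        tifffile.imwrite(
            Path(tiff_path), np.round(self.gain * scale).astype(np.uint16)
        )
        meta = {
            "gain_scale": scale,
            "reference": self.reference.tolist(),
            "mask_true_fraction": float(self.mask.mean()),
        }
        Path(json_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, tiff_path: str | Path, json_path: str | Path) -> "FlatField":
        meta = json.loads(Path(json_path).read_text())
        raw = tifffile.imread(Path(tiff_path)).astype(np.float64)
        gain = raw / float(meta["gain_scale"])
        mask = gain.min(axis=-1) > 0
        return cls(
            gain=np.where(gain > 0, gain, 1.0),
            reference=np.asarray(meta["reference"], dtype=np.float64),
            mask=mask,
        )


def _masked_gaussian(
    data: np.ndarray, mask: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian blur ignoring masked-out pixels (normalised convolution)."""
    if sigma <= 0:
        return data.copy()
    m = mask.astype(np.float64)
    num = gaussian_filter(data * m, sigma=sigma, mode="nearest")
    den = gaussian_filter(m, sigma=sigma, mode="nearest")
    out = np.zeros_like(data)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def build_flatfield(
    white: PlateImage, sigma_frac: float = DEFAULT_SIGMA_FRAC
) -> FlatField:
    """Derive the gain map from an aligned white-block image."""
    arr = white.to_float()
    mask = white.valid_mask
    if not mask.any():
        raise CalibrationError("white image has no valid pixels")
    for ch, name in enumerate("RGB"):
        frac = float(np.mean(arr[..., ch][mask] >= SATURATION_LEVEL))
        if frac > MAX_SATURATED_FRAC:
            raise CalibrationError(
                f"white image saturated: {frac:.1%} of {name} pixels at full scale"
            )
    sigma = sigma_frac * arr.shape[1]
    smoothed = np.stack(
        [_masked_gaussian(arr[..., ch], mask, sigma) for ch in range(3)], axis=-1
    )
    if np.any(smoothed[mask] <= 0):
        raise CalibrationError("white image contains zero-valued pixels after smoothing")

    gain = np.ones_like(smoothed)
    reference = np.empty(3)
    for ch in range(3):
        med = float(np.median(smoothed[..., ch][mask]))
        reference[ch] = med
        channel = smoothed[..., ch]
        g = np.ones_like(channel)
        g[mask] = med / channel[mask]
        gain[..., ch] = g

    valid = gain[mask]
    ratio = float(valid.max() / valid.min())
    if ratio >= MAX_GAIN_RATIO:
        raise CalibrationError(
            f"gain ratio {ratio:.2f} exceeds {MAX_GAIN_RATIO}: white image unusable"
        )
    return FlatField(gain=gain, reference=reference, mask=mask.copy())


def apply_flatfield(test: PlateImage, ff: FlatField) -> PlateImage:
    """Multiply the aligned test image by the gain map, clipped to 8-bit range.

    Sentinel (masked) pixels pass through unchanged; the output mask is
    the intersection of the test and flat-field masks.
    """
    arr = test.to_float()
    if arr.shape[:2] != ff.gain.shape[:2]:
        raise CalibrationError(
            f"flat-field dimensions {ff.gain.shape[:2]} do not match "
            f"image {arr.shape[:2]}"
        )
    mask = test.valid_mask & ff.mask
    out = arr.copy()
    out[mask] = np.clip(arr[mask] * ff.gain[mask], 0.0, 255.0)
    return PlateImage(
        data=out,
        mask=mask,
        provenance=f"{test.provenance}/flatfielded",
        scale_px_per_mm=test.scale_px_per_mm,
    )
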