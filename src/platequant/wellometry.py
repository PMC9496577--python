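"""Well segmentation and histogram-mode intensity readout.

Each well is reduced to three per-channel histogram modes — the intensity
with the highest frequency of occurrence in the well's RGB histograms —
and one spectrally weighted scalar intensity

    y = a*I_R + b*I_G + c*I_B,

where (a, b, c) normalise the camera's RGB sensitivities (RS, GS, BS) at
the assay's peak absorbance wavelength:

    a = RS / (RS + GS + BS),  b = GS / (...),  c = BS / (...).

The histogram mode is what makes the readout robust to glare, bubbles and
reflections: artefacts perturb a minority of pixels and never move the
most frequent value as long as the undisturbed solution colour remains
the majority.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SceneError, SegmentationError
from .geometry import DEFAULT_GEOMETRY, PlateGeometry, well_rowcol
from .image import PlateImage

#: Minimum usable pixels per well ROI before readout is considered unreliable.
MIN_ROI_PIXELS = 50

#: Fraction of the well radius retained by the segmentation ROI.  The inner
#: 70% excludes the well wall and rim shadow.
DEFAULT_ROI_MARGIN = 0.70


# ---------------------------------------------------------------------------
# Spectral weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralWeights:
    """Camera RGB sensitivities at one wavelength and the derived weights."""

    red_sensitivity: float
    green_sensitivity: float
    blue_sensitivity: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        for v in (self.red_sensitivity, self.green_sensitivity, self.blue_sensitivity):
            if not v > 0:
                raise SceneError("camera sensitivities must be strictly positive")

    @property
    def a(self) -> float:
        return self.red_sensitivity / self._total

    @property
    def b(self) -> float:
        return self.green_sensitivity / self._total

    @property
    def c(self) -> float:
        return self.blue_sensitivity / self._total

    @property
    def _total(self) -> float:
        return self.red_sensitivity + self.green_sensitivity + self.blue_sensitivity

    @property
    def abc(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def make_weights(
    red: float, green: float, blue: float, wavelength_nm: float | None = None
) -> SpectralWeights:
    """Normalise RGB sensitivities into weights summing to one."""
    return SpectralWeights(red, green, blue, wavelength_nm)


def weights_from_curve(
    curve: pd.DataFrame | str | Path, wavelength_nm: float
) -> SpectralWeights:
    """Interpolate a sensitivity curve (wavelength_nm, red, green, blue).

    The curve is a CSV/DataFrame with columns ``wavelength_nm``, ``red``,
    ``green``, ``blue``; channel sensitivities are linearly interpolated
    at the requested wavelength.
    """
    if not isinstance(curve, pd.DataFrame):
        curve = pd.read_csv(curve)
    required = {"wavelength_nm", "red", "green", "blue"}
    if not required.issubset(curve.columns):
        raise SceneError(f"sensitivity curve needs columns {sorted(required)}")
    curve = curve.sort_values("wavelength_nm")
    wl = curve["wavelength_nm"].to_numpy(float)
    if not wl[0] <= wavelength_nm <= wl[-1]:
        raise SceneError(
            f"wavelength {wavelength_nm} nm outside the curve's range "
            f"[{wl[0]}, {wl[-1]}]"
        )
    vals = [
        float(np.interp(wavelength_nm, wl, curve[ch].to_numpy(float)))
        for ch in ("red", "green", "blue")
    ]
    return make_weights(*vals, wavelength_nm=wavelength_nm)


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

ROLES = ("standard", "sample", "empty")


@dataclass
class WellSpec:
    role: str = "empty"
    concentration: float | None = None  # standards: known concentration
    dilution_factor: float = 1.0  # samples: fold dilution applied
    replicate_group: str | None = None


@dataclass
class PlateLayout:
    """Per-well role annotations on top of a :class:`PlateGeometry` grid."""

    wells: dict[str, WellSpec]
    geometry: PlateGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        ids = self.geometry.well_ids()
        full: dict[str, WellSpec] = {}
        for wid, spec in self.wells.items():
            row, col = well_rowcol(wid)
            full[f"{wid[0].upper()}{int(wid[1:])}"] = spec
        for wid in ids:
            full.setdefault(wid, WellSpec())
        unknown = set(full) - set(ids)
        if unknown:
            raise SceneError(f"layout wells outside the grid: {sorted(unknown)}")
        for wid, spec in full.items():
            if spec.role not in ROLES:
                raise SceneError(f"well {wid}: unknown role {spec.role!r}")
            if spec.role == "standard":
                if spec.concentration is None or spec.concentration < 0:
                    raise SceneError(
                        f"standard well {wid} needs a non-negative concentration"
                    )
            if spec.role == "sample" and spec.dilution_factor < 1:
                raise SceneError(f"sample well {wid}: dilution factor must be >= 1")
        self.wells = {wid: full[wid] for wid in ids}

    def standards(self) -> dict[str, float]:
        return {
            wid: s.concentration
            for wid, s in self.wells.items()
            if s.role == "standard"
        }

    def samples(self) -> dict[str, WellSpec]:
        return {wid: s for wid, s in self.wells.items() if s.role == "sample"}

    def empties(self) -> tuple[str, ...]:
        return tuple(wid for wid, s in self.wells.items() if s.role == "empty")

    # -- CSV round trip -----------------------------------------------------

    @classmethod
    def from_csv(
        cls, path: str | Path, geometry: PlateGeometry = DEFAULT_GEOMETRY
    ) -> "PlateLayout":
        df = pd.read_csv(path)
        required = {"well_id", "role"}
        if not required.issubset(df.columns):
            raise SceneError("layout CSV needs well_id and role columns")
        wells = {}
        for _, row in df.iterrows():
            conc = row.get("concentration")
            df_factor = row.get("dilution_factor")
            group = row.get("replicate_group")
            wells[str(row["well_id"])] = WellSpec(
                role=str(row["role"]).strip(),
                concentration=None if pd.isna(conc) else float(conc),
                dilution_factor=1.0 if pd.isna(df_factor) else float(df_factor),
                replicate_group=None if pd.isna(group) else str(group),
            )
        return cls(wells=wells, geometry=geometry)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "well_id": wid,
                "role": s.role,
                "concentration": s.concentration,
                "dilution_factor": s.dilution_factor,
                "replicate_group": s.replicate_group,
            }
            for wid, s in self.wells.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Segmentation and readout
# ---------------------------------------------------------------------------


def segment_wells(
    image: PlateImage,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    margin: float = DEFAULT_ROI_MARGIN,
) -> dict[str, np.ndarray]:
    """Extract each well's ROI pixels from an aligned image.

    Returns a dict of well id -> (n, 3) float array of RGB values inside
    the circular ROI (the layout radius shrunk to ``margin`` times the
    well radius), with masked (sentinel) pixels excluded.
    """
    if image.scale_px_per_mm is None:
        raise SegmentationError("segmentation requires an aligned image with a scale")
    if not 0 < margin <= 1:
        raise SegmentationError("ROI margin must be in (0, 1]")
    scale = image.scale_px_per_mm
    data = image.to_float()
    valid = image.valid_mask
    h, w = data.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    rois: dict[str, np.ndarray] = {}
    r_px = geometry.well_radius_mm * margin * scale
    for wid in geometry.well_ids():
        cx_mm, cy_mm = geometry.well_center(wid)
        cx, cy = cx_mm * scale, cy_mm * scale
        sel = (
            ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2)
            & valid
        )
        n = int(sel.sum())
        if n < MIN_ROI_PIXELS:
            raise SegmentationError(
                f"well {wid}: only {n} usable pixels in its ROI (need "
                f">= {MIN_ROI_PIXELS})"
            )
        rois[wid] = data[sel]
    return rois


def mode_intensity(values: np.ndarray) -> int:
    """Histogram mode of one channel's ROI values over 256 integer bins.

    Values are rounded to the nearest integer level; ties between bins
    with equal counts break toward the lower intensity.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise SegmentationError("mode of an empty pixel set is undefined")
    levels = np.clip(np.round(values), 0, 255).astype(np.intp)
    counts = np.bincount(levels, minlength=256)
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximum


def weighted_intensity(modes: np.ndarray, weights: SpectralWeights) -> float:
    """Combine the three channel modes with the spectral weights."""
    modes = np.asarray(modes, dtype=np.float64)
    return float(weights.abc @ modes)


@dataclass
class WellReading:
    """One well's readout: channel modes, weighted intensity, QC counts."""

    well_id: str
    i_red: int
    i_green: int
    i_blue: int
    y: float
    pixel_count: int
    mode_share: float  # fraction of ROI pixels within +-1 of the mode bins


def read_wells(
    image: PlateImage,
    weights: SpectralWeights,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    margin: float = DEFAULT_ROI_MARGIN,
) -> pd.DataFrame:
    """Segment and reduce all 96 wells; returns one row per well.

    Columns: well_id, i_red, i_green, i_blue, y, pixel_count, mode_share.
    """
    rois = segment_wells(image, geometry=geometry, margin=margin)
    rows = []
    for wid, px in rois.items():
        modes = np.array([mode_intensity(px[:, ch]) for ch in range(3)])
        share = float(
            np.mean(
                np.all(
                    np.abs(np.round(px) - modes[None, :]) <= 1,
                    axis=1,
                )
            )
        )
        rows.append(
            {
                "well_id": wid,
                "i_red": int(modes[0]),
                "i_green": int(modes[1]),
                "i_blue": int(modes[2]),
                "y": weighted_intensity(modes, weights),
                "pixel_count": px.shape[0],
                "mode_share": share,
            }
        )
    return pd.DataFrame(rows)
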