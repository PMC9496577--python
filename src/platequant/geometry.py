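"""Plate and device geometry in the canonical millimetre frame.

The canonical frame has its origin at the top-left corner of the plate
footprint, x increasing to the right and y increasing downward, in
millimetres.  Well positions follow the ANSI/SLAS 96-well layout: 9 mm
pitch with well A1 centred at (14.38 mm, 11.24 mm).  The four dark
fiducial squares sit near the plate corners, clear of the well grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import SceneError

ROW_LABELS = "ABCDEFGH"
#: The 96 well identifiers in row-major order: A1..A12, B1..B12, ... H12.
WELL_IDS: tuple[str, ...] = tuple(
    f"{row}{col}" for row in ROW_LABELS for col in range(1, 13)
)

FIDUCIAL_LABELS = ("tl", "tr", "bl", "br")


def well_rowcol(well_id: str) -> tuple[int, int]:
    """Map a well id like ``"C7"`` to zero-based (row, col) indices."""
    wid = well_id.strip().upper()
    if len(wid) < 2 or wid[0] not in ROW_LABELS or not wid[1:].isdigit():
        raise SceneError(f"malformed well id {well_id!r}")
    row = ROW_LABELS.index(wid[0])
    col = int(wid[1:]) - 1
    if not 0 <= col < 12:
        raise SceneError(f"well id {well_id!r} outside the 8x12 grid")
    return row, col


def well_name(row: int, col: int) -> str:
    return f"{ROW_LABELS[row]}{col + 1}"


@dataclass(frozen=True)
class PlateGeometry:
    """Physical geometry of the plate and the device's fiducial marks.

    Defaults follow the ANSI/SLAS footprint (127.76 x 85.48 mm outer
    dimensions).  Fiducial positions are configurable because they belong
    to the device, not the plate standard.
    """

    plate_width_mm: float = 127.76
    plate_height_mm: float = 85.48
    n_rows: int = 8
    n_cols: int = 12
    pitch_mm: float = 9.0
    a1_offset_mm: tuple[float, float] = (14.38, 11.24)
    well_radius_mm: float = 3.4
    fiducial_centers_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tl": (6.0, 6.0),
            "tr": (121.76, 6.0),
            "bl": (6.0, 79.48),
            "br": (121.76, 79.48),
        }
    )
    fiducial_size_mm: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "plate_width_mm",
            "plate_height_mm",
            "pitch_mm",
            "well_radius_mm",
            "fiducial_size_mm",
        ):
            if getattr(self, name) <= 0:
                raise SceneError(f"{name} must be strictly positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise SceneError("grid dimensions must be strictly positive")
        if self.pitch_mm <= 2 * self.well_radius_mm:
            raise SceneError("well ROIs overlap: pitch must exceed the well diameter")
        x0, y0 = self.a1_offset_mm
        r = self.well_radius_mm
        x_max = x0 + (self.n_cols - 1) * self.pitch_mm + r
        y_max = y0 + (self.n_rows - 1) * self.pitch_mm + r
        if x0 - r < 0 or y0 - r < 0:
            raise SceneError("well grid extends past the plate's top-left edge")
        if x_max > self.plate_width_mm or y_max > self.plate_height_mm:
            raise SceneError("well grid does not fit inside the plate bounds")
        if set(self.fiducial_centers_mm) != set(FIDUCIAL_LABELS):
            raise SceneError(f"fiducial centers must be keyed by {FIDUCIAL_LABELS}")

    def well_center(self, well_id: str) -> tuple[float, float]:
        row, col = well_rowcol(well_id)
        x0, y0 = self.a1_offset_mm
        return (x0 + col * self.pitch_mm, y0 + row * self.pitch_mm)

    def well_ids(self) -> tuple[str, ...]:
        return tuple(
            well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)
        )

    def fiducial_points(self) -> dict[str, tuple[float, float]]:
        """Fiducial centre coordinates keyed by quadrant label."""
        return dict(self.fiducial_centers_mm)

    def fiducial_area_mm2(self) -> float:
        return self.fiducial_size_mm**2

    def distance(self, well_a: str, well_b: str) -> float:
        xa, ya = self.well_center(well_a)
        xb, yb = self.well_center(well_b)
        return math.hypot(xa - xb, ya - yb)


DEFAULT_GEOMETRY = PlateGeometry()
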