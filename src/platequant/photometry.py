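"""Incident-light estimation from empty wells and optical density.

A filled well's transmitted intensity is its weighted readout y; the
incident intensity is estimated from nearby *empty* wells, which stay at
the unabsorbed illumination level:

1. histogram the integer-rounded weighted intensities of all 96 wells
   (256 levels); the most frequent value w is the global empty-well
   intensity (empty wells cluster, dyed wells scatter; ties break toward
   the brighter bin since the empties are the bright repeated value);
2. within the 5x5 well neighbourhood of each well (truncated at the
   plate edges, centre included), keep intensities >= 0.95*w — the local
   empty set — and average them into the local incident estimate wL;
   if no neighbour qualifies, fall back to w and flag the well;
3. OD = -log10(wL / y), the sign convention of the source device (an
   absorbing solution has OD <= 0; the standard-curve slope absorbs the
   sign).  ``conventional=True`` flips to textbook absorbance.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import SegmentationError
from .geometry import well_rowcol

#: Intensity histogram levels (8-bit readout).
N_LEVELS = 256
#: A neighbour counts as empty at or above this fraction of the global mode.
EMPTY_FRACTION = 0.95
#: Half-width of the square well neighbourhood (5x5 -> 2).
WINDOW_HALF = 2


def global_empty_mode(y_values: np.ndarray) -> int:
    """Most frequent integer-rounded weighted intensity across the wells.

    Ties between equally frequent levels break toward the *higher*
    intensity: the repeated value of interest is the bright empty-well
    cluster.
    """
    y = np.asarray(y_values, dtype=np.float64).ravel()
    if y.size == 0:
        raise SegmentationError("no well intensities to histogram")
    levels = np.clip(np.round(y), 0, N_LEVELS - 1).astype(np.intp)
    counts = np.bincount(levels, minlength=N_LEVELS)
    return int(N_LEVELS - 1 - np.argmax(counts[::-1]))


def local_incident(
    y_grid: np.ndarray, row: int, col: int, w: float
) -> tuple[float, int, int, bool]:
    """Mean empty-well intensity in the 5x5 window around (row, col).

    Returns ``(wL, P, Q, fallback)`` where P is the truncated window
    cardinality, Q the number of qualifying empty wells, and fallback is
    True when no neighbour reached ``0.95*w`` and ``wL = w`` was used.
    """
    n_rows, n_cols = y_grid.shape
    window = y_grid[
        max(0, row - WINDOW_HALF) : row + WINDOW_HALF + 1,
        max(0, col - WINDOW_HALF) : col + WINDOW_HALF + 1,
    ].ravel()
    s_w = window[window >= EMPTY_FRACTION * w]
    p = int(window.size)
    q = int(s_w.size)
    if q == 0:
        return float(w), p, q, True
    return float(s_w.mean()), p, q, False


def incident_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Per-well incident estimates for a full plate of readings.

    ``readings`` needs columns ``well_id`` and ``y``; the output adds
    ``w`` (global empty mode), ``wL``, window cardinalities ``P`` and
    ``Q``, and the ``fallback_incident`` flag.
    """
    y_by_well = dict(zip(readings["well_id"], readings["y"]))
    rows_cols = [well_rowcol(wid) for wid in readings["well_id"]]
    n_rows = max(r for r, _ in rows_cols) + 1
    n_cols = max(c for _, c in rows_cols) + 1
    y_grid = np.full((n_rows, n_cols), np.nan)
    for wid, (r, c) in zip(readings["well_id"], rows_cols):
        y_grid[r, c] = y_by_well[wid]
    if np.isnan(y_grid).any():
        raise SegmentationError("incident estimation needs a full grid of readings")

    w = global_empty_mode(readings["y"].to_numpy())
    out = []
    for wid, (r, c) in zip(readings["well_id"], rows_cols):
        wl, p, q, fb = local_incident(y_grid, r, c, w)
        out.append(
            {"well_id": wid, "w": w, "wL": wl, "P": p, "Q": q, "fallback_incident": fb}
        )
    return pd.DataFrame(out)


def optical_density(y: float, w_local: float, conventional: bool = False) -> float:
    """OD of one well: ``-log10(wL / y)`` (device convention).

    With ``conventional=True`` returns ``+log10(wL / y)``, the textbook
    absorbance.  A fully dark well (y <= 0) has no finite OD and must be
    flagged saturated by the caller.
    """
    if y <= 0:
        raise SegmentationError("optical density undefined for y <= 0 (saturated)")
    if w_local <= 0:
        raise SegmentationError("incident estimate must be positive")
    od = -math.log10(w_local / y)
    return -od if conventional else od


def od_table(readings: pd.DataFrame, conventional: bool = False) -> pd.DataFrame:
    """Weighted intensities -> per-well OD with QC flags.

    Output columns: well_id, y, w, wL, P, Q, od, flags (semicolon-joined
    strings among ``saturated`` / ``fallback-incident``); saturated wells
    carry ``od = NaN``.
    """
    inc = incident_table(readings)
    merged = readings.merge(inc, on="well_id", validate="one_to_one")
    ods = []
    flags = []
    for _, row in merged.iterrows():
        fl = []
        if row["fallback_incident"]:
            fl.append("fallback-incident")
        if row["y"] <= 0:
            fl.append("saturated")
            ods.append(np.nan)
        else:
            ods.append(optical_density(row["y"], row["wL"], conventional=conventional))
        flags.append(";".join(fl))
    merged["od"] = ods
    merged["flags"] = flags
    return merged[["well_id", "y", "w", "wL", "P", "Q", "od", "flags"]]
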