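"""Standard-curve fitting, concentration prediction and replicate stats.

The calibrator concentrations relate exponentially to optical density,
so the fit is ordinary least squares of ln(concentration) on OD:

    ln(Cd) = x * OD + z        =>        Cd = exp(x * OD + z)

The zero calibrator cannot enter the log fit (ln 0); it is kept for QC —
its OD should sit at ~0.  A sample diluted df-fold before the assay
reports the final concentration C = Cd * df.  Replicates use the sample
standard deviation (n-1 denominator; for n = 2 this is |x1 - x2|/sqrt(2)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assays import AssayConfig
from .errors import FitError

MIN_FIT_POINTS = 3


@dataclass
class StandardCurve:
    """Fitted coefficients of ln(Cd) = x*OD + z with diagnostics."""

    x: float  # slope
    z: float  # intercept
    r_squared: float
    residuals: np.ndarray  # per-standard residuals of ln C
    od_range: tuple[float, float]  # OD span of the fitted standards
    conc_range: tuple[float, float]  # concentration span incl. the zero standard
    conventional_od: bool = False
    n_points: int = 0

    def predict_cd(self, od: float) -> float:
        return math.exp(self.x * od + self.z)

    def od_of(self, cd: float) -> float:
        if cd <= 0:
            raise FitError("concentration must be positive to invert the curve")
        return (math.log(cd) - self.z) / self.x

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "z": self.z,
            "r_squared": self.r_squared,
            "od_range": list(self.od_range),
            "conc_range": list(self.conc_range),
            "conventional_od": self.conventional_od,
            "n_points": self.n_points,
        }


def fit_standard_curve(
    standards: list[tuple[float, float]],
    assay: AssayConfig | None = None,
    conventional_od: bool = False,
) -> StandardCurve:
    """OLS fit of ln(concentration) on OD over the nonzero standards.

    ``standards`` is a list of (concentration, OD) pairs; pairs with zero
    concentration are excluded from the fit but still widen the curve's
    concentration span used by the range flags.
    """
    pairs = [(float(c), float(od)) for c, od in standards]
    if any(c < 0 for c, _ in pairs):
        raise FitError("standard concentrations must be non-negative")
    fit_pairs = [(c, od) for c, od in pairs if c > 0]
    if len(fit_pairs) < MIN_FIT_POINTS:
        raise FitError(
            f"need at least {MIN_FIT_POINTS} nonzero standards, got {len(fit_pairs)}"
        )
    conc = np.array([c for c, _ in fit_pairs])
    ods = np.array([od for _, od in fit_pairs])
    if np.ptp(ods) < 1e-12:
        raise FitError("degenerate standards: zero variance in OD")
    ln_c = np.log(conc)
    res = stats.linregress(ods, ln_c)
    fitted = res.slope * ods + res.intercept
    low = 0.0 if any(c == 0 for c, _ in pairs) else float(conc.min())
    if assay is not None:
        low, high = assay.detection_range
    else:
        high = float(conc.max())
    return StandardCurve(
        x=float(res.slope),
        z=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=ln_c - fitted,
        od_range=(float(ods.min()), float(ods.max())),
        conc_range=(low, high),
        conventional_od=conventional_od,
        n_points=len(fit_pairs),
    )


@dataclass
class AssayResult:
    """One well's quantification: diluted and final concentration + flags."""

    well_id: str
    od: float
    cd: float  # diluted concentration (on the curve)
    df: float  # dilution factor
    c: float  # final concentration = cd * df
    replicate_group: str | None = None
    flags: list[str] = field(default_factory=list)


def predict_concentration(
    od: float,
    curve: StandardCurve,
    df: float = 1.0,
    well_id: str = "",
    replicate_group: str | None = None,
) -> AssayResult:
    """Convert one OD into concentrations with range/extrapolation flags.

    Flags never fail the run: ``above-range`` / ``below-range`` compare
    the *diluted* concentration against the detection range (further
    dilution and re-testing is the remedy for above-range readings);
    ``extrapolated`` marks ODs outside the fitted standards' span.
    """
    if df < 1:
        raise FitError("dilution factor must be >= 1")
    cd = curve.predict_cd(od)
    c = cd * df
    flags = []
    lo, hi = curve.conc_range
    if cd > hi:
        flags.append("above-range")
    elif cd < lo:
        flags.append("below-range")
    od_lo, od_hi = curve.od_range
    if not od_lo <= od <= od_hi:
        flags.append("extrapolated")
    return AssayResult(
        well_id=well_id,
        od=od,
        cd=cd,
        df=df,
        c=c,
        replicate_group=replicate_group,
        flags=flags,
    )


def replicate_stats(values: list[float]) -> tuple[float, float | None]:
    """Mean and sample SD (n-1) of replicate concentrations.

    A single replicate yields the mean with SD ``None`` (undefined).
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise FitError("no replicate values")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    return mean, float(vals.std(ddof=1))


def dilution_series_report(results: list[AssayResult]) -> pd.DataFrame:
    """Replicate table across dilution levels with a recommended factor.

    Groups results by dilution factor and reports (df, n, mean, sd,
    in_range, recommended).  The recommended level is the in-range level
    with the smallest replicate SD (ties break toward the lowest df);
    levels with any out-of-range diluted concentration are excluded —
    over-diluting pushes Cd below the limit of detection and the spread
    grows again.
    """
    if not results:
        raise FitError("no results to summarise")
    by_df: dict[float, list[AssayResult]] = {}
    for r in results:
        by_df.setdefault(float(r.df), []).append(r)
    rows = []
    for df_value in sorted(by_df):
        group = by_df[df_value]
        mean, sd = replicate_stats([r.c for r in group])
        in_range = not any(
            "below-range" in r.flags or "above-range" in r.flags for r in group
        )
        rows.append(
            {
                "df": df_value,
                "n": len(group),
                "mean": mean,
                "sd": sd,
                "in_range": in_range,
            }
        )
    table = pd.DataFrame(rows)
    eligible = table[table["in_range"] & table["sd"].notna()]
    table["recommended"] = False
    if len(eligible):
        best = eligible.sort_values(["sd", "df"]).index[0]
        table.loc[best, "recommended"] = True
    return table


def concentration_sensitivity(
    curve: StandardCurve, concentration: float, incident: float, df: float = 1.0
) -> float:
    """|dC/dy| at a given final concentration: curve steepness in
    concentration units per intensity unit.

    On an exponential curve a fixed intensity perturbation moves the
    concentration more at the high end than mid-range: C grows while the
    transmitted intensity y shrinks, so |dC/dy| = C*|x|/(y*ln10) rises
    monotonically with concentration.
    """
    if concentration <= 0 or incident <= 0:
        raise FitError("concentration and incident intensity must be positive")
    cd = concentration / df
    od = curve.od_of(cd)
    if curve.conventional_od:
        od = -od
    y = incident * 10.0**od
    return concentration * abs(curve.x) / (y * math.log(10.0))
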