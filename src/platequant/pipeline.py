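"""End-to-end orchestration: align -> calibrate -> segment -> intensities
-> OD -> fit -> concentrations, plus file-based run configuration."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import AssayConfig, load_assay
from .errors import FitError, PlatequantError
from .flatfield import apply_flatfield, build_flatfield
from .geometry import DEFAULT_GEOMETRY, PlateGeometry
from .image import PlateImage
from .photometry import od_table
from .quantify import (
    AssayResult,
    StandardCurve,
    fit_standard_curve,
    predict_concentration,
    replicate_stats,
)
from .registration import align, detect_fiducials, fit_transform
from .wellometry import PlateLayout, read_wells

logger = logging.getLogger("platequant")

#: Canonical-frame sampling density used for rectified images.
DEFAULT_SCALE_PX_PER_MM = 4.0
#: Fixed decimal places in every emitted CSV, for reproducible diffs.
CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class PipelineResult:
    """Everything one analysis run produced, in memory."""

    transform_residual_mm: float
    readings: pd.DataFrame
    od: pd.DataFrame
    curve: StandardCurve
    results: pd.DataFrame
    qc: dict


def run_pipeline(
    plate: PlateImage,
    white: PlateImage,
    layout: PlateLayout,
    assay: AssayConfig,
    geometry: PlateGeometry | None = None,
    scale: float = DEFAULT_SCALE_PX_PER_MM,
    conventional_od: bool = False,
) -> PipelineResult:
    """Run the full measurement chain on in-memory images."""
    geometry = geometry if geometry is not None else layout.geometry
    standards = layout.standards()
    if not any(c > 0 for c in standards.values()):
        raise FitError("layout defines no nonzero standards to fit")
    if not layout.empties():
        raise FitError("local incident estimation needs at least one empty well")

    fiducials = detect_fiducials(plate)
    transform = fit_transform(fiducials, geometry.fiducial_points())
    logger.info("registration residual %.2e mm", transform.residual_mm)
    plate_al = align(plate, transform, scale, geometry=geometry)
    white_al = align(white, transform, scale, geometry=geometry)

    ff = build_flatfield(white_al)
    corrected = apply_flatfield(plate_al, ff)

    readings = read_wells(corrected, assay.weights, geometry=geometry)
    od = od_table(readings, conventional=conventional_od)
    od_by_well = dict(zip(od["well_id"], od["od"]))

    pairs = [(conc, od_by_well[wid]) for wid, conc in standards.items()]
    curve = fit_standard_curve(
        [(c, o) for c, o in pairs if not np.isnan(o)],
        assay=assay,
        conventional_od=conventional_od,
    )

    results: list[AssayResult] = []
    for wid, spec in layout.samples().items():
        res = predict_concentration(
            od_by_well[wid],
            curve,
            df=spec.dilution_factor,
            well_id=wid,
            replicate_group=spec.replicate_group,
        )
        results.append(res)

    rows = [
        {
            "well_id": r.well_id,
            "replicate_group": r.replicate_group,
            "od": r.od,
            "cd": r.cd,
            "df": r.df,
            "c": r.c,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    results_df = pd.DataFrame(
        rows,
        columns=["well_id", "replicate_group", "od", "cd", "df", "c", "flags"],
    )
    if len(results_df):
        means, sds = {}, {}
        for group, sub in results_df.groupby("replicate_group", dropna=True):
            mean, sd = replicate_stats(list(sub["c"]))
            means[group], sds[group] = mean, sd
        results_df["group_mean"] = results_df["replicate_group"].map(means)
        results_df["group_sd"] = results_df["replicate_group"].map(sds)
    else:
        results_df["group_mean"] = []
        results_df["group_sd"] = []

    zero_ods = [od_by_well[wid] for wid, c in standards.items() if c == 0]
    qc = {
        "fiducial_residual_mm": transform.residual_mm,
        "fallback_incident_count": int(od["flags"].str.contains("fallback").sum()),
        "saturated_wells": list(od.loc[od["flags"].str.contains("saturated"), "well_id"]),
        "r_squared": curve.r_squared,
        "zero_standard_od": zero_ods,
        "flagged_wells": {
            r.well_id: r.flags for r in results if r.flags
        },
    }
    return PipelineResult(
        transform_residual_mm=transform.residual_mm,
        readings=readings,
        od=od,
        curve=curve,
        results=results_df,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# File-based runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and options for one file-based analysis run."""

    test_image: Path
    white_image: Path
    layout_csv: Path
    assay: str  # preset name or YAML path
    out_dir: Path
    conventional_od: bool = False
    scale: float = DEFAULT_SCALE_PX_PER_MM
    geometry: PlateGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def provenance(self) -> dict:
        digest = hashlib.sha256(
            json.dumps(
                {
                    "test_image": str(self.test_image),
                    "white_image": str(self.white_image),
                    "layout": str(self.layout_csv),
                    "assay": str(self.assay),
                    "conventional_od": self.conventional_od,
                    "scale": self.scale,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16]
        return {"tool_version": __version__, "config_hash": digest}


def analyze(config: RunConfig) -> PipelineResult:
    """File-based full pipeline; writes CSV/JSON outputs and a QC report."""
    if not Path(config.white_image).exists():
        raise PlatequantError("calibration image required: white image not found")
    for path, what in (
        (config.test_image, "test image"),
        (config.layout_csv, "layout CSV"),
    ):
        if not Path(path).exists():
            raise PlatequantError(f"{what} not found: {path}")
    plate = PlateImage.read_png(config.test_image, provenance="test")
    white = PlateImage.read_png(config.white_image, provenance="white-calibration")
    layout = PlateLayout.from_csv(config.layout_csv, geometry=config.geometry)
    assay = load_assay(config.assay)

    result = run_pipeline(
        plate,
        white,
        layout,
        assay,
        geometry=config.geometry,
        scale=config.scale,
        conventional_od=config.conventional_od,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    result.readings.to_csv(
        out / "well_readings.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    result.od.to_csv(out / "od.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    curve_doc = {**result.curve.to_dict(), **prov}
    (out / "curve.json").write_text(json.dumps(curve_doc, indent=2))
    result.results.to_csv(
        out / "results.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )

    lines = [
        f"platequant {prov['tool_version']} QC report (config {prov['config_hash']})",
        f"assay: {assay.name} ({assay.units}, {assay.wavelength_nm:.0f} nm)",
        f"fiducial residual: {result.qc['fiducial_residual_mm']:.6f} mm",
        f"standard-curve R^2: {result.qc['r_squared']:.6f}",
        f"fallback incident wells: {result.qc['fallback_incident_count']}",
        f"saturated wells: {', '.join(result.qc['saturated_wells']) or 'none'}",
        "zero-standard OD: "
        + (
            ", ".join(f"{v:.6f}" for v in result.qc["zero_standard_od"])
            or "no zero standard"
        ),
        "flagged wells: "
        + (
            "; ".join(
                f"{wid} [{','.join(fl)}]"
                for wid, fl in result.qc["flagged_wells"].items()
            )
            or "none"
        ),
    ]
    (out / "qc_report.txt").write_text("\n".join(lines) + "\n")
    return result
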