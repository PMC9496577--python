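"""Synthetic 96-well plate photographs with exact ground truth.

Emulates a white opaque 96-well microplate photographed from above inside
an enclosed reader: four dark corner fiducial squares, an 8x12 well grid,
per-well dye colour following an absorbance model, smooth illumination
from four corner LEDs, sensor noise, and glare/bubble artefacts.  A
paired featureless white-block render under the same illumination and
camera supplies the flat-field calibration image.

Forward colour model
--------------------
A well at concentration ``c`` receives a target absorbance ``A(c)`` from
the assay's dye response law and is rendered with per-channel
transmittance ``10**(-s * alpha_ch)``; the scalar ``s`` is solved per
well so that the spectrally weighted intensity satisfies exactly

    y(c) = y_blank * 10**(-A(c))         (before quantisation),

with channel absorptivities ``alpha_ch`` normalised so the assay's
absorbance-wavelength channel has ``alpha = 1`` and attenuates most.
This makes the downstream optical-density and standard-curve stages
analytically checkable against the generator's parameters.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .assays import AssayConfig, load_assay
from .errors import SceneError
from .geometry import DEFAULT_GEOMETRY, PlateGeometry, well_name, well_rowcol
from .image import PlateImage
from .wellometry import PlateLayout, WellSpec

#: Reflected radiance (0-255 scale) of the white plate / white block under
#: unit illumination.
WHITE_LEVEL = 250.0
#: Fiducial squares are near-black in every channel.
FIDUCIAL_LEVEL = 30.0
#: Well wall / rim shadow ring between 90% and 100% of the well radius.
RIM_LEVEL = 235.0
#: Device interior visible outside the plate footprint.
OUTSIDE_LEVEL = 210.0
#: Fraction of the well radius filled by solution (inside the rim ring).
WELL_CORE_FRACTION = 0.9
#: Multiplicative attenuation under a bubble artefact.
BUBBLE_FACTOR = 0.6


# ---------------------------------------------------------------------------
# Illumination and camera models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IlluminationModel:
    """Sum of four inverse-power falloff sources at the plate corners.

    Each corner LED i contributes ``I_i / (1 + (d_i / falloff_mm)**m)``
    where ``d_i`` is the in-plane distance to the source.  The field is
    normalised by its maximum over the plate footprint so the brightest
    plate point sits at relative intensity 1.
    """

    source_positions_mm: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (127.76, 0.0),
        (0.0, 85.48),
        (127.76, 85.48),
    )
    relative_intensity: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    falloff_mm: float = 45.0
    falloff_exponent: float = 2.0

    def __post_init__(self) -> None:
        if len(self.source_positions_mm) != len(self.relative_intensity):
            raise SceneError("one relative intensity per light source required")
        if self.falloff_mm <= 0 or self.falloff_exponent < 0:
            raise SceneError("illumination falloff parameters must be positive")
        if min(self.relative_intensity) <= 0:
            raise SceneError("source intensities must be strictly positive")

    def field_at(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Unnormalised illumination at the given mm coordinates."""
        x = np.asarray(x_mm, dtype=np.float64)
        y = np.asarray(y_mm, dtype=np.float64)
        total = np.zeros(np.broadcast(x, y).shape)
        for (sx, sy), inten in zip(self.source_positions_mm, self.relative_intensity):
            d = np.hypot(x - sx, y - sy)
            total += inten / (1.0 + (d / self.falloff_mm) ** self.falloff_exponent)
        return total

    def plate_max(self, geometry: PlateGeometry) -> float:
        """Maximum of the field over the plate footprint (dense grid)."""
        gx = np.linspace(0.0, geometry.plate_width_mm, 257)
        gy = np.linspace(0.0, geometry.plate_height_mm, 173)
        xx, yy = np.meshgrid(gx, gy)
        return float(self.field_at(xx, yy).max())

    def normalized_at(
        self, x_mm: np.ndarray, y_mm: np.ndarray, geometry: PlateGeometry
    ) -> np.ndarray:
        return self.field_at(x_mm, y_mm) / self.plate_max(geometry)


UNIFORM_ILLUMINATION = IlluminationModel(falloff_exponent=0.0)


@dataclass(frozen=True)
class CameraModel:
    """Projective map from plate millimetres to pixel coordinates."""

    homography_mm_to_px: tuple[tuple[float, float, float], ...]
    image_size: tuple[int, int] = (704, 480)  # (width, height)

    def __post_init__(self) -> None:
        h = np.asarray(self.homography_mm_to_px, dtype=np.float64)
        if h.shape != (3, 3) or abs(np.linalg.det(h)) < 1e-12:
            raise SceneError("camera homography must be an invertible 3x3 matrix")
        w, hgt = self.image_size
        if w <= 0 or hgt <= 0:
            raise SceneError("image size must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.homography_mm_to_px, dtype=np.float64)

    def project(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (n, 2) mm points to (n, 2) pixel (x, y) coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        ones = np.ones((pts.shape[0], 1))
        hom = (self.matrix @ np.hstack([pts, ones]).T).T
        return hom[:, :2] / hom[:, 2:3]


def make_camera(
    scale_px_per_mm: float = 5.0,
    rotation_deg: float = 1.5,
    translation_px: tuple[float, float] = (18.0, 14.0),
    perspective: tuple[float, float] = (2.5e-4, 1.5e-4),
    image_size: tuple[int, int] = (704, 480),
) -> CameraModel:
    """Build a mildly rotated, mildly projective camera model.

    The default perspective terms scale the far plate edge ~4% smaller —
    a slightly off-axis camera — so all eight homography degrees of
    freedom are exercised and identifiable from the fiducials.
    """
    th = math.radians(rotation_deg)
    s = scale_px_per_mm
    tx, ty = translation_px
    gx, gy = perspective
    h = (
        (s * math.cos(th), -s * math.sin(th), tx),
        (s * math.sin(th), s * math.cos(th), ty),
        (gx, gy, 1.0),
    )
    return CameraModel(homography_mm_to_px=h, image_size=image_size)


DEFAULT_CAMERA = make_camera()


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise and optical artefacts added to a render."""

    sigma_rgb: tuple[float, float, float] = (2.0, 2.0, 2.0)
    glare_count: int = 4
    glare_radius_mm: tuple[float, float] = (0.5, 1.2)
    bubble_count: int = 2
    bubble_radius_mm: tuple[float, float] = (0.4, 0.8)

    def __post_init__(self) -> None:
        if min(self.sigma_rgb) < 0:
            raise SceneError("noise sigma must be non-negative")
        if self.glare_count < 0 or self.bubble_count < 0:
            raise SceneError("artefact counts must be non-negative")


NOISELESS = NoiseModel(sigma_rgb=(0.0, 0.0, 0.0), glare_count=0, bubble_count=0)


# ---------------------------------------------------------------------------
# Scene specification and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Full description of a synthetic plate photograph."""

    assay: AssayConfig
    concentrations: dict[str, float] = field(default_factory=dict)
    geometry: PlateGeometry = DEFAULT_GEOMETRY
    illumination: IlluminationModel = IlluminationModel()
    noise: NoiseModel = NoiseModel()
    camera: CameraModel = DEFAULT_CAMERA
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ids = self.geometry.well_ids()
        conc: dict[str, float] = {}
        specified = []
        for wid, c in self.concentrations.items():
            key = well_name(*well_rowcol(wid))
            c = float(c)
            if c < 0:
                raise SceneError(f"well {key}: concentration must be non-negative")
            conc[key] = c
            specified.append(key)
        unknown = set(conc) - set(ids)
        if unknown:
            raise SceneError(f"concentration map has unknown wells: {sorted(unknown)}")
        for wid in ids:
            conc.setdefault(wid, 0.0)
        self.concentrations = {wid: conc[wid] for wid in ids}
        self.specified_wells = tuple(specified)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path, assay_ref: str | None = None) -> None:
        cfg = {
            "assay": assay_ref if assay_ref is not None else self.assay.name,
            "concentrations": {
                wid: self.concentrations[wid] for wid in self.specified_wells
            },
            "illumination": {
                "source_positions_mm": [
                    list(p) for p in self.illumination.source_positions_mm
                ],
                "relative_intensity": list(self.illumination.relative_intensity),
                "falloff_mm": self.illumination.falloff_mm,
                "falloff_exponent": self.illumination.falloff_exponent,
            },
            "noise": {
                "sigma_rgb": list(self.noise.sigma_rgb),
                "glare_count": self.noise.glare_count,
                "glare_radius_mm": list(self.noise.glare_radius_mm),
                "bubble_count": self.noise.bubble_count,
                "bubble_radius_mm": list(self.noise.bubble_radius_mm),
            },
            "camera": {
                "homography_mm_to_px": [
                    list(r) for r in self.camera.homography_mm_to_px
                ],
                "image_size": list(self.camera.image_size),
            },
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        assay = load_assay(cfg["assay"])
        kwargs: dict = {}
        if "illumination" in cfg:
            il = cfg["illumination"]
            kwargs["illumination"] = IlluminationModel(
                source_positions_mm=tuple(tuple(p) for p in il["source_positions_mm"]),
                relative_intensity=tuple(il["relative_intensity"]),
                falloff_mm=float(il["falloff_mm"]),
                falloff_exponent=float(il["falloff_exponent"]),
            )
        if "noise" in cfg:
            nz = cfg["noise"]
            kwargs["noise"] = NoiseModel(
                sigma_rgb=tuple(nz["sigma_rgb"]),
                glare_count=int(nz["glare_count"]),
                glare_radius_mm=tuple(nz["glare_radius_mm"]),
                bubble_count=int(nz["bubble_count"]),
                bubble_radius_mm=tuple(nz["bubble_radius_mm"]),
            )
        if "camera" in cfg:
            cam = cfg["camera"]
            kwargs["camera"] = CameraModel(
                homography_mm_to_px=tuple(
                    tuple(r) for r in cam["homography_mm_to_px"]
                ),
                image_size=tuple(cam["image_size"]),
            )
        return cls(
            assay=assay,
            concentrations=dict(cfg.get("concentrations", {})),
            rng_seed=int(cfg.get("rng_seed", 0)),
            **kwargs,
        )


@dataclass
class GroundTruth:
    """Exactly what was drawn: the oracle for every downstream stage."""

    concentrations: dict[str, float]
    dye_rgb: dict[str, tuple[float, float, float]]  # noiseless colour, unquantised
    fiducials_px: dict[str, tuple[float, float]]
    homography_mm_to_px: np.ndarray

    def write(self, out_dir: str | Path, stem: str = "truth") -> None:
        out = Path(out_dir)
        rows = [
            {
                "well_id": wid,
                "concentration": self.concentrations[wid],
                "R": self.dye_rgb[wid][0],
                "G": self.dye_rgb[wid][1],
                "B": self.dye_rgb[wid][2],
            }
            for wid in self.concentrations
        ]
        pd.DataFrame(rows).to_csv(out / f"{stem}.csv", index=False, float_format="%.6f")
        meta = {
            "homography_mm_to_px": np.asarray(self.homography_mm_to_px).tolist(),
            "fiducials_px": {k: list(v) for k, v in self.fiducials_px.items()},
        }
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Dye forward model
# ---------------------------------------------------------------------------


def target_absorbance(concentration: float, assay: AssayConfig) -> float:
    """Target absorbance of the weighted intensity for one concentration."""
    if concentration < 0:
        raise SceneError("concentration must be non-negative")
    if concentration == 0:
        return 0.0
    dye = assay.dye
    if dye.response == "beer_lambert":
        return dye.extinction * concentration
    # log_linear: ln c = slope * OD + intercept with OD = -A
    a = (dye.intercept - math.log(concentration)) / dye.slope
    return max(0.0, a)


def dye_color(concentration: float, assay: AssayConfig) -> np.ndarray:
    """Noiseless RGB colour (0-255 floats) of a well at this concentration.

    Solves the per-well attenuation scalar so the weighted intensity of
    the colour equals ``y_blank * 10**(-A)`` exactly; channels attenuate
    in proportion to the assay's relative absorptivities, the absorbance
    channel most.
    """
    a_target = target_absorbance(concentration, assay)
    blank = np.asarray(assay.dye.blank_rgb, dtype=np.float64)
    if a_target == 0.0:
        return blank.copy()
    w = assay.weights.abc
    alpha = np.asarray(assay.dye.absorptivities, dtype=np.float64)
    y_blank = float(w @ blank)
    y_target = y_blank * 10.0 ** (-a_target)

    def deficit(s: float) -> float:
        return float(w @ (blank * 10.0 ** (-s * alpha))) - y_target

    lo, hi = a_target * (1 - 1e-12), a_target / alpha.min() + 1e-9
    s = brentq(deficit, lo, hi, xtol=1e-13, rtol=1e-15)
    return np.clip(blank * 10.0 ** (-s * alpha), 0.0, 255.0)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _pixel_mm_grids(camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    w, h = camera.image_size
    hinv = np.linalg.inv(camera.matrix)
    xx, yy = np.meshgrid(
        np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64)
    )
    den = hinv[2, 0] * xx + hinv[2, 1] * yy + hinv[2, 2]
    x_mm = (hinv[0, 0] * xx + hinv[0, 1] * yy + hinv[0, 2]) / den
    y_mm = (hinv[1, 0] * xx + hinv[1, 1] * yy + hinv[1, 2]) / den
    return x_mm, y_mm


def _check_wells_visible(spec: SceneSpec) -> None:
    g = spec.geometry
    r = g.well_radius_mm
    w, h = spec.camera.image_size
    for wid in g.well_ids():
        cx, cy = g.well_center(wid)
        edge = np.array(
            [[cx - r, cy], [cx + r, cy], [cx, cy - r], [cx, cy + r]]
        )
        px = spec.camera.project(edge)
        if (
            px[:, 0].min() < 0
            or px[:, 0].max() > w - 1
            or px[:, 1].min() < 0
            or px[:, 1].max() > h - 1
        ):
            raise SceneError(f"well {wid} projects outside the image bounds")


def _reflectance(
    spec: SceneSpec, x_mm: np.ndarray, y_mm: np.ndarray
) -> np.ndarray:
    """Noiseless, unlit scene colour at each pixel (H, W, 3)."""
    g = spec.geometry
    img = np.full(x_mm.shape + (3,), OUTSIDE_LEVEL, dtype=np.float64)
    on_plate = (
        (x_mm >= 0)
        & (x_mm <= g.plate_width_mm)
        & (y_mm >= 0)
        & (y_mm <= g.plate_height_mm)
    )
    img[on_plate] = WHITE_LEVEL

    half = g.fiducial_size_mm / 2.0
    for cx, cy in g.fiducial_centers_mm.values():
        # anti-aliased square: edge coverage from the signed box distance,
        # scaled by the local pixel density so registration sees sub-pixel
        # edges rather than jagged binary ones
        probe = spec.camera.project(
            np.array([[cx - 0.5, cy], [cx + 0.5, cy], [cx, cy - 0.5], [cx, cy + 0.5]])
        )
        px_per_mm = 0.5 * (
            np.linalg.norm(probe[1] - probe[0]) + np.linalg.norm(probe[3] - probe[2])
        )
        d_mm = np.maximum(np.abs(x_mm - cx), np.abs(y_mm - cy)) - half
        alpha = np.clip(0.5 - d_mm * px_per_mm, 0.0, 1.0)
        img = img * (1.0 - alpha[..., None]) + FIDUCIAL_LEVEL * alpha[..., None]

    # nearest-well assignment: the grid is regular, so rounding the offset
    # to the pitch lattice finds the only candidate well per pixel
    x0, y0 = g.a1_offset_mm
    col = np.clip(np.round((x_mm - x0) / g.pitch_mm), 0, g.n_cols - 1).astype(int)
    row = np.clip(np.round((y_mm - y0) / g.pitch_mm), 0, g.n_rows - 1).astype(int)
    dx = x_mm - (x0 + col * g.pitch_mm)
    dy = y_mm - (y0 + row * g.pitch_mm)
    d2 = dx * dx + dy * dy
    r = g.well_radius_mm
    in_well = d2 <= r * r
    in_core = d2 <= (WELL_CORE_FRACTION * r) ** 2
    img[in_well & ~in_core] = RIM_LEVEL

    colors = np.empty((g.n_rows, g.n_cols, 3))
    for wid in g.well_ids():
        rr, cc = well_rowcol(wid)
        colors[rr, cc] = dye_color(spec.concentrations[wid], spec.assay)
    img[in_core] = colors[row[in_core], col[in_core]]
    return img


def _draw_artifacts(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float, float]], list[tuple[float, float, float]]]:
    """Sample glare and bubble discs (centre mm, radius mm) inside wells."""
    g = spec.geometry
    ids = g.well_ids()

    def sample(count: int, radius_range: tuple[float, float]):
        discs = []
        for _ in range(count):
            wid = ids[int(rng.integers(len(ids)))]
            cx, cy = g.well_center(wid)
            rho = 0.5 * g.well_radius_mm * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            radius = rng.uniform(*radius_range)
            discs.append((cx + rho * math.cos(phi), cy + rho * math.sin(phi), radius))
        return discs

    glare = sample(spec.noise.glare_count, spec.noise.glare_radius_mm)
    bubbles = sample(spec.noise.bubble_count, spec.noise.bubble_radius_mm)
    return glare, bubbles


def render_plate(spec: SceneSpec) -> tuple[PlateImage, GroundTruth]:
    """Render the plate photograph and its exact ground truth."""
    _check_wells_visible(spec)
    rng = np.random.default_rng(spec.rng_seed)
    glare, bubbles = _draw_artifacts(spec, rng)

    x_mm, y_mm = _pixel_mm_grids(spec.camera)
    radiance = _reflectance(spec, x_mm, y_mm)
    lum = spec.illumination.normalized_at(x_mm, y_mm, spec.geometry)
    radiance *= lum[..., None]

    for bx, by, br in bubbles:
        m = (x_mm - bx) ** 2 + (y_mm - by) ** 2 <= br * br
        radiance[m] *= BUBBLE_FACTOR
    sigma = np.asarray(spec.noise.sigma_rgb, dtype=np.float64)
    if sigma.max() > 0:
        radiance += rng.normal(0.0, 1.0, radiance.shape) * sigma[None, None, :]
    for gx, gy, gr in glare:
        m = (x_mm - gx) ** 2 + (y_mm - gy) ** 2 <= gr * gr
        radiance[m] = 255.0

    data = np.round(np.clip(radiance, 0.0, 255.0)).astype(np.uint8)
    image = PlateImage(data=data, provenance="synthetic")

    fid_px = {
        label: tuple(spec.camera.project([center])[0])
        for label, center in spec.geometry.fiducial_centers_mm.items()
    }
    truth = GroundTruth(
        concentrations=dict(spec.concentrations),
        dye_rgb={
            wid: tuple(dye_color(c, spec.assay))
            for wid, c in spec.concentrations.items()
        },
        fiducials_px=fid_px,
        homography_mm_to_px=spec.camera.matrix.copy(),
    )
    return image, truth


def render_white_block(spec: SceneSpec) -> PlateImage:
    """Render the white calibration target under the same optics."""
    rng = np.random.default_rng([spec.rng_seed, 1])
    x_mm, y_mm = _pixel_mm_grids(spec.camera)
    lum = spec.illumination.normalized_at(x_mm, y_mm, spec.geometry)
    radiance = np.full(x_mm.shape + (3,), WHITE_LEVEL) * lum[..., None]
    sigma = np.asarray(spec.noise.sigma_rgb, dtype=np.float64)
    if sigma.max() > 0:
        radiance += rng.normal(0.0, 1.0, radiance.shape) * sigma[None, None, :]
    data = np.round(np.clip(radiance, 0.0, 255.0)).astype(np.uint8)
    return PlateImage(data=data, provenance="white-calibration")


# ---------------------------------------------------------------------------
# Convenience scene builders
# ---------------------------------------------------------------------------


def standards_scene(
    assay: AssayConfig,
    seed: int = 0,
    hold_out: int | None = None,
    samples: dict[str, tuple[float, float, str]] | None = None,
    noise: NoiseModel = NoiseModel(),
    illumination: IlluminationModel = IlluminationModel(),
    camera: CameraModel = DEFAULT_CAMERA,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
) -> tuple[SceneSpec, PlateLayout]:
    """Standards across row A (the conventional plate map), plus samples.

    ``hold_out`` marks the given standard (index into the assay's series)
    as an unknown sample instead, with dilution factor 1 — the held-out
    recovery protocol.  ``samples`` places extra dyed wells:
    well id -> (diluted concentration actually in the well, dilution
    factor, replicate group).
    """
    stds = assay.standards
    if len(stds) > geometry.n_cols:
        raise SceneError("standard series does not fit across one row")
    conc: dict[str, float] = {}
    wells: dict[str, WellSpec] = {}
    for i, c in enumerate(stds):
        wid = well_name(0, i)
        conc[wid] = c
        if hold_out is not None and i == hold_out:
            wells[wid] = WellSpec(
                role="sample", dilution_factor=1.0, replicate_group="heldout"
            )
        else:
            wells[wid] = WellSpec(role="standard", concentration=c)
    for wid, (c_diluted, df, group) in (samples or {}).items():
        if wid in conc:
            raise SceneError(f"sample well {wid} collides with a standard")
        conc[wid] = c_diluted
        wells[wid] = WellSpec(
            role="sample", dilution_factor=df, replicate_group=group
        )
    spec = SceneSpec(
        assay=assay,
        concentrations=conc,
        geometry=geometry,
        illumination=illumination,
        noise=noise,
        camera=camera,
        rng_seed=seed,
    )
    layout = PlateLayout(wells=wells, geometry=geometry)
    return spec, layout


def scene_layout(spec: SceneSpec) -> PlateLayout:
    """Default layout for a bare scene: every specified well is a standard."""
    wells = {
        wid: WellSpec(role="standard", concentration=spec.concentrations[wid])
        for wid in spec.specified_wells
    }
    return PlateLayout(wells=wells, geometry=spec.geometry)


def write_bundle(
    spec: SceneSpec,
    out_dir: str | Path,
    layout: PlateLayout | None = None,
) -> dict[str, Path]:
    """Render and write plate.png, white.png, truth.csv/json, layout.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, truth = render_plate(spec)
    white = render_white_block(spec)
    image.write_png(out / "plate.png")
    white.write_png(out / "white.png")
    truth.write(out, stem="truth")
    if layout is None:
        layout = scene_layout(spec)
    layout.to_csv(out / "layout.csv")
    return {
        "plate": out / "plate.png",
        "white": out / "white.png",
        "truth_csv": out / "truth.csv",
        "truth_json": out / "truth.json",
        "layout": out / "layout.csv",
    }
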