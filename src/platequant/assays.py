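"""Assay configurations: spectral weights, standard series, dye model.

Two presets ship with the package:

* ``creatinine`` — Jaffe reaction readout at 490 nm (red complex), camera
  sensitivities RS=0.07, GS=0.82, BS=0.66, standards 0-1.77 mmol/L.
* ``glucose`` — glucose-oxidase/HRP readout at 560 nm (pink product),
  camera sensitivities RS=0.13, GS=0.83, BS=0.11, standards 0-32 mg/dL.

The ``dye`` block parameterises the synthetic forward colour model used
by the plate-image generator; it has no role when analysing real
photographs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import SceneError
from .wellometry import SpectralWeights, make_weights

#: Unit conversion for creatinine: 1 mg/dL = 0.0884 mmol/L
#: (consistent with the paired values 20 mg/dL = 1.77 mmol/L).
CREATININE_MMOL_PER_MG_DL = 0.0884

#: Supported concentration->absorbance response laws for the synthetic dye.
DYE_RESPONSES = ("log_linear", "beer_lambert")


@dataclass(frozen=True)
class DyeModel:
    """Synthetic forward colour model for one assay.

    The model maps a concentration to a target absorbance A (of the
    spectrally weighted intensity: y = y_blank * 10**(-A)) and splits it
    across the RGB channels via per-channel absorptivities, normalised so
    the channel carrying the assay's absorbance wavelength has
    absorptivity 1 and therefore attenuates most.

    Response laws:

    * ``log_linear`` — A = (intercept - ln c) / slope with slope < 0, so
      ln(concentration) is exactly linear in measured OD; this mirrors the
      empirically exponential standard curves of real kits.
    * ``beer_lambert`` — A = extinction * c, the textbook law for an
      ideal absorber.
    """

    response: str = "log_linear"
    slope: float | None = None  # log_linear: x in ln c = x*OD + z (x < 0)
    intercept: float | None = None  # log_linear: z
    extinction: float | None = None  # beer_lambert: k in A = k*c
    absorptivities: tuple[float, float, float] = (1.0, 1.0, 1.0)
    blank_rgb: tuple[float, float, float] = (250.0, 250.0, 250.0)

    def __post_init__(self) -> None:
        if self.response not in DYE_RESPONSES:
            raise SceneError(f"unknown dye response {self.response!r}")
        if self.response == "log_linear":
            if self.slope is None or self.intercept is None or self.slope >= 0:
                raise SceneError("log_linear dye needs slope < 0 and an intercept")
        else:
            if self.extinction is None or self.extinction <= 0:
                raise SceneError("beer_lambert dye needs extinction > 0")
        alphas = self.absorptivities
        if len(alphas) != 3 or min(alphas) <= 0:
            raise SceneError("absorptivities must be three positive values")
        if abs(max(alphas) - 1.0) > 1e-9:
            raise SceneError("absorptivities are normalised to max = 1")
        if len(self.blank_rgb) != 3 or min(self.blank_rgb) <= 0:
            raise SceneError("blank colour must be three positive channel values")


@dataclass(frozen=True)
class AssayConfig:
    """Everything the pipeline needs to know about one colorimetric assay."""

    name: str
    units: str
    wavelength_nm: float
    weights: SpectralWeights
    standards: tuple[float, ...]
    detection_range: tuple[float, float]
    dye: DyeModel = field(default_factory=DyeModel)
    incubation_note: str = ""
    diluent: str = ""

    def __post_init__(self) -> None:
        stds = tuple(float(s) for s in self.standards)
        if list(stds) != sorted(stds):
            raise SceneError("standards must be sorted ascending")
        if sum(1 for s in stds if s > 0) < 3:
            raise SceneError("need at least 3 nonzero standards for fitting")
        if any(s < 0 for s in stds):
            raise SceneError("standard concentrations must be non-negative")
        low, high = self.detection_range
        if not low < high:
            raise SceneError("detection range must satisfy low < high")
        object.__setattr__(self, "standards", stds)


def _assay_from_dict(cfg: dict) -> AssayConfig:
    sens = cfg["sensitivities"]
    weights = make_weights(
        float(sens["red"]),
        float(sens["green"]),
        float(sens["blue"]),
        wavelength_nm=float(cfg["wavelength_nm"]),
    )
    dye_cfg = cfg.get("dye", {})
    dye = DyeModel(
        response=dye_cfg.get("response", "log_linear"),
        slope=dye_cfg.get("slope"),
        intercept=dye_cfg.get("intercept"),
        extinction=dye_cfg.get("extinction"),
        absorptivities=tuple(dye_cfg.get("absorptivities", (1.0, 1.0, 1.0))),
        blank_rgb=tuple(dye_cfg.get("blank_rgb", (250.0, 250.0, 250.0))),
    )
    return AssayConfig(
        name=str(cfg["name"]),
        units=str(cfg["units"]),
        wavelength_nm=float(cfg["wavelength_nm"]),
        weights=weights,
        standards=tuple(float(s) for s in cfg["standards"]),
        detection_range=tuple(float(v) for v in cfg["detection_range"]),
        dye=dye,
        incubation_note=str(cfg.get("incubation", "")),
        diluent=str(cfg.get("diluent", "")),
    )


def load_assay(name_or_path: str | Path) -> AssayConfig:
    """Load an assay config by preset name or YAML path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("platequant.data") / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise SceneError(
                f"unknown assay {name_or_path!r}: not a preset and not a YAML file"
            )
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    return _assay_from_dict(cfg)


def assay_to_yaml(assay: AssayConfig, path: str | Path) -> None:
    cfg = {
        "name": assay.name,
        "units": assay.units,
        "wavelength_nm": assay.wavelength_nm,
        "sensitivities": {
            "red": assay.weights.red_sensitivity,
            "green": assay.weights.green_sensitivity,
            "blue": assay.weights.blue_sensitivity,
        },
        "standards": list(assay.standards),
        "detection_range": list(assay.detection_range),
        "dye": {
            "response": assay.dye.response,
            "slope": assay.dye.slope,
            "intercept": assay.dye.intercept,
            "extinction": assay.dye.extinction,
            "absorptivities": list(assay.dye.absorptivities),
            "blank_rgb": list(assay.dye.blank_rgb),
        },
        "incubation": assay.incubation_note,
        "diluent": assay.diluent,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
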