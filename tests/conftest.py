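"""Shared fixtures: assay presets and pre-rendered synthetic bundles.

Renders are session-scoped — they are deterministic and read-only, and
several test modules probe different stages of the same scene.
"""
from __future__ import annotations

from dataclasses import dataclass

import pytest

import platequant as pq


@dataclass
class Bundle:
    spec: pq.SceneSpec
    layout: pq.PlateLayout
    image: pq.PlateImage
    truth: pq.GroundTruth
    white: pq.PlateImage


def _render(spec: pq.SceneSpec, layout: pq.PlateLayout) -> Bundle:
    image, truth = pq.render_plate(spec)
    white = pq.render_white_block(spec)
    return Bundle(spec=spec, layout=layout, image=image, truth=truth, white=white)


@pytest.fixture(scope="session")
def creatinine() -> pq.AssayConfig:
    return pq.load_assay("creatinine")


@pytest.fixture(scope="session")
def glucose() -> pq.AssayConfig:
    return pq.load_assay("glucose")


@pytest.fixture(scope="session")
def flat_bundle(creatinine) -> Bundle:
    """Noiseless render under spatially uniform illumination."""
    spec, layout = pq.standards_scene(
        creatinine,
        seed=11,
        noise=pq.NOISELESS,
        illumination=pq.UNIFORM_ILLUMINATION,
    )
    return _render(spec, layout)


@pytest.fixture(scope="session")
def corner_bundle(creatinine) -> Bundle:
    """Noiseless render under the corner-LED illumination gradient."""
    spec, layout = pq.standards_scene(creatinine, seed=12, noise=pq.NOISELESS)
    return _render(spec, layout)


@pytest.fixture(scope="session")
def noisy_bundle(creatinine) -> Bundle:
    """Default noise model (sensor noise + glare + bubbles), held-out standard."""
    spec, layout = pq.standards_scene(creatinine, seed=13, hold_out=1)
    return _render(spec, layout)


@pytest.fixture(scope="session")
def empty_plate_bundle(creatinine) -> Bundle:
    """All 96 wells empty, corner-LED illumination, no noise."""
    spec = pq.SceneSpec(
        assay=creatinine, concentrations={}, noise=pq.NOISELESS, rng_seed=14
    )
    layout = pq.PlateLayout(wells={}, geometry=spec.geometry)
    return _render(spec, layout)
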