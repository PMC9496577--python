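"""Synthetic plate generator: forward model, determinism, ground truth."""
from __future__ import annotations

import numpy as np
import pytest

import platequant as pq
from platequant.assays import AssayConfig, DyeModel
from platequant.errors import SceneError
from platequant.synth import WHITE_LEVEL


def _beer_lambert_assay(c_max: float = 1.77) -> AssayConfig:
    """Assay whose dye follows A = k*c with 10**(-k*c_max) = 0.1."""
    base = pq.load_assay("creatinine")
    dye = DyeModel(
        response="beer_lambert",
        extinction=1.0 / c_max,
        absorptivities=base.dye.absorptivities,
        blank_rgb=base.dye.blank_rgb,
    )
    return AssayConfig(
        name="creatinine-bl",
        units=base.units,
        wavelength_nm=base.wavelength_nm,
        weights=base.weights,
        standards=base.standards,
        detection_range=base.detection_range,
        dye=dye,
    )


class TestDyeColor:
    def test_zero_concentration_is_blank(self, creatinine):
        assert np.array_equal(
            pq.dye_color(0.0, creatinine), np.array(creatinine.dye.blank_rgb)
        )

    def test_negative_concentration_rejected(self, creatinine):
        with pytest.raises(SceneError, match="non-negative"):
            pq.dye_color(-0.1, creatinine)

    def test_weighted_intensity_matches_target_absorbance(self, creatinine, glucose):
        for assay in (creatinine, glucose):
            w = assay.weights.abc
            y_blank = float(w @ np.asarray(assay.dye.blank_rgb))
            for c in assay.standards[1:]:
                y = float(w @ pq.dye_color(c, assay))
                expected = y_blank * 10 ** (-pq.target_absorbance(c, assay))
                assert y == pytest.approx(expected, rel=1e-9)

    def test_absorbance_channel_attenuates_most(self, creatinine):
        color = pq.dye_color(1.0, creatinine)
        blank = np.asarray(creatinine.dye.blank_rgb)
        attenuation = color / blank
        # green carries alpha = 1 for the 490 nm Jaffe readout
        assert np.argmin(attenuation) == 1
        order = np.argsort(creatinine.dye.absorptivities)
        assert np.all(np.diff(attenuation[order]) <= 0)

    def test_beer_lambert_tenth_at_top_standard(self):
        """k chosen so 10**(-k*c)=0.1 at c_max: rendered well reads 0.1*y_blank."""
        assay = _beer_lambert_assay(c_max=1.77)
        w = assay.weights.abc
        y_blank = float(w @ np.asarray(assay.dye.blank_rgb))
        # forward formula, noiseless
        y_direct = float(w @ pq.dye_color(1.77, assay))
        assert y_direct == pytest.approx(0.1 * y_blank, rel=1e-9)
        # pipeline readout on a noiseless uniform render
        spec = pq.SceneSpec(
            assay=assay,
            concentrations={"D6": 1.77},
            noise=pq.NOISELESS,
            illumination=pq.UNIFORM_ILLUMINATION,
            rng_seed=0,
        )
        image, _ = pq.render_plate(spec)
        fid = pq.detect_fiducials(image)
        transform = pq.fit_transform(fid, spec.geometry.fiducial_points())
        aligned = pq.align(image, transform, 4.0)
        readings = pq.read_wells(aligned, assay.weights)
        y_well = float(readings.set_index("well_id").loc["D6", "y"])
        assert y_well == pytest.approx(0.1 * y_blank, abs=1.0)  # quantisation

    @pytest.mark.parametrize("response", ["log_linear", "beer_lambert"])
    def test_weighted_intensity_strictly_decreasing(self, creatinine, response):
        assay = creatinine if response == "log_linear" else _beer_lambert_assay()
        w = assay.weights.abc
        concs = np.linspace(0.25, 1.77, 12)
        ys = [float(w @ pq.dye_color(c, assay)) for c in concs]
        assert np.all(np.diff(ys) < 0)
        # doubling the concentration decreases y
        assert float(w @ pq.dye_color(1.0, assay)) > float(
            w @ pq.dye_color(2.0, assay)
        )


class TestRenderPlate:
    def test_seeded_determinism(self, creatinine):
        spec, _ = pq.standards_scene(creatinine, seed=21)
        img1, _ = pq.render_plate(spec)
        img2, _ = pq.render_plate(spec)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(
            pq.render_white_block(spec).data, pq.render_white_block(spec).data
        )

    def test_different_seed_changes_noise(self, creatinine):
        spec1, _ = pq.standards_scene(creatinine, seed=1)
        spec2, _ = pq.standards_scene(creatinine, seed=2)
        assert not np.array_equal(
            pq.render_plate(spec1)[0].data, pq.render_plate(spec2)[0].data
        )

    def test_fiducial_centroids_match_analytic_projection(self, flat_bundle):
        fid = pq.detect_fiducials(flat_bundle.image)
        for label, (gx, gy) in flat_bundle.truth.fiducials_px.items():
            x, y = fid.centroids[label]
            assert abs(x - gx) < 0.5 and abs(y - gy) < 0.5

    def test_ground_truth_keys_cover_plate(self, flat_bundle):
        assert set(flat_bundle.truth.concentrations) == set(pq.WELL_IDS)
        assert set(flat_bundle.truth.dye_rgb) == set(pq.WELL_IDS)

    def test_empty_plate_reads_od_near_zero(self, empty_plate_bundle, creatinine):
        b = empty_plate_bundle
        fid = pq.detect_fiducials(b.image)
        transform = pq.fit_transform(fid, b.spec.geometry.fiducial_points())
        aligned = pq.align(b.image, transform, 4.0)
        white = pq.align(b.white, transform, 4.0)
        corrected = pq.apply_flatfield(aligned, pq.build_flatfield(white))
        readings = pq.read_wells(corrected, creatinine.weights)
        ods = pq.od_table(readings)["od"]
        assert np.nanmax(np.abs(ods)) < 0.02

    def test_well_projected_outside_image_is_an_error(self, creatinine):
        camera = pq.make_camera(scale_px_per_mm=5.0, image_size=(300, 480))
        with pytest.raises(SceneError, match="well .* outside the image"):
            pq.render_plate(
                pq.SceneSpec(assay=creatinine, concentrations={}, camera=camera)
            )

    def test_negative_concentration_rejected_in_scene(self, creatinine):
        with pytest.raises(SceneError, match="non-negative"):
            pq.SceneSpec(assay=creatinine, concentrations={"A1": -1.0})

    def test_singular_homography_rejected(self):
        with pytest.raises(SceneError, match="invertible"):
            pq.CameraModel(homography_mm_to_px=tuple(map(tuple, np.zeros((3, 3)))))


class TestWhiteBlock:
    def test_uniform_illumination_constant_up_to_quantisation(self, creatinine):
        spec = pq.SceneSpec(
            assay=creatinine,
            concentrations={},
            illumination=pq.UNIFORM_ILLUMINATION,
            noise=pq.NOISELESS,
        )
        white = pq.render_white_block(spec)
        assert np.all(white.data == round(WHITE_LEVEL))

    def test_corner_falloff_matches_illumination_model(self, creatinine):
        spec = pq.SceneSpec(assay=creatinine, concentrations={}, noise=pq.NOISELESS)
        white = pq.render_white_block(spec)
        g = spec.geometry
        center_mm = np.array([[g.plate_width_mm / 2, g.plate_height_mm / 2]])
        corner_mm = np.array([[5.0, 5.0]])
        expected_ratio = float(
            spec.illumination.field_at(*center_mm[0])
            / spec.illumination.field_at(*corner_mm[0])
        )
        px_c = spec.camera.project(center_mm)[0].round().astype(int)
        px_k = spec.camera.project(corner_mm)[0].round().astype(int)
        measured = float(white.data[px_c[1], px_c[0], 1]) / float(
            white.data[px_k[1], px_k[0], 1]
        )
        assert measured == pytest.approx(expected_ratio, rel=0.02)


class TestSceneYaml:
    def test_round_trip(self, creatinine, tmp_path):
        spec, _ = pq.standards_scene(creatinine, seed=7)
        path = tmp_path / "scene.yaml"
        spec.to_yaml(path)
        loaded = pq.SceneSpec.from_yaml(path)
        assert loaded.rng_seed == spec.rng_seed
        assert loaded.concentrations == spec.concentrations
        assert np.allclose(loaded.camera.matrix, spec.camera.matrix)
        img1, _ = pq.render_plate(spec)
        img2, _ = pq.render_plate(loaded)
        assert np.array_equal(img1.data, img2.data)
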