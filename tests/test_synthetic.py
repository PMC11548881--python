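"""Generator tests: geometry, vesicle placement, forward optics, I/O."""

import dataclasses

import numpy as np
import pytest

import endoquant as eq
from endoquant.errors import CapacityError, ParameterError

from conftest import make_clean_scene, noiseless_image


class TestBuildCellGeometry:
    def test_circular_cell_encloses_expected_area(self):
        cfg = eq.GeometryConfig(cell_radius=10.0, nucleus_radius=4.0, irregularity=0.0)
        scene = eq.build_cell_geometry(cfg, seed=1)
        area = scene.polygon().area
        assert area == pytest.approx(np.pi * 100.0, rel=0.01)

    def test_deterministic_for_fixed_seed(self):
        cfg = eq.GeometryConfig()
        a = eq.build_cell_geometry(cfg, seed=3)
        b = eq.build_cell_geometry(cfg, seed=3)
        np.testing.assert_array_equal(a.pm_contour, b.pm_contour)
        assert a.nucleus_center == b.nucleus_center

    def test_different_seeds_differ(self):
        cfg = eq.GeometryConfig()
        a = eq.build_cell_geometry(cfg, seed=3)
        b = eq.build_cell_geometry(cfg, seed=4)
        assert not np.array_equal(a.pm_contour, b.pm_contour)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(cell_radius=10.0, nucleus_radius=12.0), "nucleus_radius"),
            (dict(cell_radius=-1.0), "cell_radius"),
            (dict(nucleus_radius=0.0), "nucleus_radius"),
        ],
    )
    def test_invalid_radii_raise_naming_field(self, kwargs, match):
        with pytest.raises(ParameterError, match=match):
            eq.build_cell_geometry(eq.GeometryConfig(**kwargs), seed=1)

    def test_scene_invariants_hold(self):
        scene = make_clean_scene(n_vesicles=3)
        scene.validate()  # simple contour, nucleus and vesicles enclosed


class TestPlaceVesicles:
    def _scene(self):
        return eq.build_cell_geometry(eq.GeometryConfig(), seed=1)

    def test_requested_count_with_ground_truth(self):
        spec = eq.VesicleSpec(count=45, rho={"protein": 0.20, "reference_dye": 1.0})
        scene = eq.place_vesicles(self._scene(), spec, seed=2)
        assert len(scene.vesicles) == 45
        for v in scene.vesicles:
            assert v.membrane_density == {"protein": 0.20, "reference_dye": 1.0}

    def test_zero_count_leaves_scene_unchanged(self):
        base = self._scene()
        out = eq.place_vesicles(base, eq.VesicleSpec(count=0, rho={}), seed=2)
        assert out.vesicles == []
        np.testing.assert_array_equal(out.pm_contour, base.pm_contour)

    def test_receptor_enrichment_truth_recorded(self):
        spec = eq.VesicleSpec(
            count=20,
            rho={"protein": 0.28, "reference_dye": 1.0, "receptor": 3.0},
        )
        scene = eq.place_vesicles(self._scene(), spec, seed=5)
        assert all(v.membrane_density["receptor"] == 3.0 for v in scene.vesicles)

    def test_per_vesicle_truth_sequences(self):
        rho = np.linspace(0.1, 0.9, 9)
        spec = eq.VesicleSpec(count=9, rho={"protein": rho, "reference_dye": 1.0})
        scene = eq.place_vesicles(self._scene(), spec, seed=2)
        got = [v.membrane_density["protein"] for v in scene.vesicles]
        np.testing.assert_allclose(got, rho)

    def test_clearances_respected(self):
        spec = eq.VesicleSpec(count=12, rho={"protein": 0.2, "reference_dye": 1.0})
        scene = eq.place_vesicles(self._scene(), spec, seed=7)
        boundary = scene.polygon().exterior
        from shapely.geometry import Point

        for i, v in enumerate(scene.vesicles):
            assert boundary.distance(Point(*v.center)) >= max(2 * v.radius, spec.pm_clearance)
            d_nuc = np.hypot(
                v.center[0] - scene.nucleus_center[0],
                v.center[1] - scene.nucleus_center[1],
            )
            assert d_nuc >= scene.nucleus_radius + v.radius
            for w in scene.vesicles[i + 1:]:
                d = np.hypot(v.center[0] - w.center[0], v.center[1] - w.center[1])
                assert d >= v.radius + w.radius + spec.separation

    def test_capacity_error_reports_achieved_count(self):
        spec = eq.VesicleSpec(
            count=500, rho={"protein": 0.2, "reference_dye": 1.0},
            radius_range=(0.6, 0.6), max_attempts_per_vesicle=30,
        )
        with pytest.raises(CapacityError) as err:
            eq.place_vesicles(self._scene(), spec, seed=2)
        assert 0 < err.value.achieved < 500


class TestRenderImage:
    def test_empty_scene_renders_dark(self):
        cfg = eq.GeometryConfig(
            pm_density={"protein": 0.0, "reference_dye": 0.0},
            cytosol_level={"protein": 0.0, "reference_dye": 0.0},
        )
        scene = eq.build_cell_geometry(cfg, seed=1)
        imaging = eq.ImagingConfig.for_roles(("protein", "reference_dye"))
        field = eq.render_field(scene, imaging)
        assert np.all(field == 0.0)
        noisy = eq.render_image(scene, imaging, seed=0)
        assert abs(noisy.pixels.astype(float).mean()) < imaging.read_noise_sd

    def test_equal_densities_make_channels_proportional(self):
        # rho_protein = rho_ref: identical geometry, so the noiseless
        # channels differ only by the PM-density scale factor
        scene = make_clean_scene(rho=1.0, radius=0.4)
        scene = dataclasses.replace(
            scene, pm_density={"protein": 5.0e3, "reference_dye": 2.0e4}
        )
        img = noiseless_image(scene)
        ratio = 2.0e4 / 5.0e3
        np.testing.assert_allclose(
            ratio * img.channel("protein"), img.channel("reference_dye"), rtol=1e-12
        )

    def test_photon_scale_linearity(self):
        scene = make_clean_scene()
        roles = tuple(scene.channels)
        f1 = eq.render_field(scene, eq.ImagingConfig.for_roles(roles, photon_scale=1.0))
        f2 = eq.render_field(scene, eq.ImagingConfig.for_roles(roles, photon_scale=2.0))
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    @pytest.mark.parametrize("sigma", [0.05, 0.15, 0.3])
    def test_total_photon_rate_conserved_under_blur(self, sigma):
        scene = make_clean_scene(cytosol=2.7e3)
        roles = tuple(scene.channels)
        sharp = eq.render_field(scene, eq.ImagingConfig.for_roles(roles, psf_sigma=0.0))
        blurred = eq.render_field(scene, eq.ImagingConfig.for_roles(roles, psf_sigma=sigma))
        np.testing.assert_allclose(
            blurred.sum(axis=(1, 2)), sharp.sum(axis=(1, 2)), rtol=1e-6
        )

    def test_noisy_render_deterministic_per_seed(self):
        scene = make_clean_scene(cytosol=2.7e3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels))
        a = eq.render_image(scene, imaging, seed=9)
        b = eq.render_image(scene, imaging, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = eq.render_image(scene, imaging, seed=10)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_noisy_raster_is_integer_within_bit_depth(self):
        scene = make_clean_scene(cytosol=2.7e3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels), bit_depth=8)
        img = eq.render_image(scene, imaging, seed=1)
        assert img.pixels.dtype == np.uint8
        assert img.pixels.max() <= 255

    def test_unknown_channel_role_rejected(self):
        scene = make_clean_scene()
        imaging = eq.ImagingConfig.for_roles(("protein", "reference_dye", "marker"))
        with pytest.raises(ParameterError, match="marker"):
            eq.render_field(scene, imaging)


class TestImagingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(pixel_size=0.0), dict(psf_sigma=-0.1), dict(bit_depth=12)]
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ParameterError):
            eq.ImagingConfig.for_roles(("protein", "reference_dye"), **kwargs)


class TestDatasetRoundTrip:
    def test_write_then_read_is_bit_exact(self, tmp_path):
        scene = make_clean_scene(cytosol=2.7e3, n_vesicles=3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels))
        img = eq.render_image(scene, imaging, seed=4)
        eq.write_dataset(img, scene, tmp_path / "cell", seeds={"render": 4})
        back = eq.read_dataset(tmp_path / "cell")
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.pixel_size == img.pixel_size
        assert back.channel_roles == img.channel_roles

    def test_truth_json_round_trips_scene(self, tmp_path):
        scene = make_clean_scene(n_vesicles=3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels))
        img = eq.render_image(scene, imaging, seed=4)
        eq.write_dataset(img, scene, tmp_path / "cell")
        back = eq.read_dataset(tmp_path / "cell").scene_truth
        assert len(back.vesicles) == len(scene.vesicles)
        np.testing.assert_allclose(back.pm_contour, scene.pm_contour)
        for a, b in zip(back.vesicles, scene.vesicles):
            assert a.center == pytest.approx(b.center)
            assert a.membrane_density == b.membrane_density

    def test_recorded_seed_regenerates_identical_raster(self, tmp_path):
        import json

        scene = make_clean_scene(cytosol=2.7e3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels))
        img = eq.render_image(scene, imaging, seed=11)
        paths = eq.write_dataset(img, scene, tmp_path / "cell", seeds={"render": 11})
        meta = json.loads(paths["json"].read_text())
        redo = eq.render_image(
            eq.synthetic.scene_from_dict(meta["scene"]), imaging,
            seed=meta["seeds"]["render"],
        )
        np.testing.assert_array_equal(redo.pixels, img.pixels)
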