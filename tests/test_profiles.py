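"""Measurement-layer tests: profiles, PM reference, ROIs, the D estimator."""

import numpy as np
import pytest

import endoquant as eq
from endoquant.errors import (
    DegenerateReferenceError,
    GeometryError,
    InsufficientDataError,
    UnmeasurableVesicleError,
)

from conftest import make_clean_scene, noiseless_image


def constant_profile(value, length=3.0, px=0.1):
    n = int(np.floor(length / px)) + 1
    pos = (np.arange(n) - (n - 1) / 2.0) * px
    return eq.LineProfile(
        positions=pos, intensity=np.full(n, float(value)),
        line_length=length, center=(0.0, 0.0), angle=0.0,
    )


class TestExtractLineProfile:
    def test_uniform_image_gives_constant_profile(self, uniform_image):
        prof = eq.extract_line_profile(uniform_image, "protein", (5.0, 5.0), 0.7)
        np.testing.assert_allclose(prof.intensity, 7.0)

    def test_sample_count_is_length_over_pitch_plus_one(self, uniform_image):
        prof = eq.extract_line_profile(uniform_image, "protein", (5.0, 5.0), 0.0, 3.0)
        assert prof.positions.size == 31
        np.testing.assert_allclose(prof.positions[0], -1.5)
        np.testing.assert_allclose(prof.positions[-1], 1.5)
        assert np.all(np.diff(prof.positions) > 0)
        np.testing.assert_allclose(prof.positions + prof.positions[::-1], 0.0, atol=1e-12)

    def test_line_exiting_image_raises(self, uniform_image):
        with pytest.raises(GeometryError):
            eq.extract_line_profile(uniform_image, "protein", (0.5, 5.0), 0.0, 3.0)

    def test_profile_matches_field_sampled_independently(self):
        # oracle: bilinear interpolation of the noiseless field written out
        # by hand at each sample position
        scene = make_clean_scene(rho=0.5, radius=0.4)
        img = noiseless_image(scene)
        v = scene.vesicles[0]
        prof = eq.extract_line_profile(img, "reference_dye", v.center, 0.3, 3.0)
        plane = img.channel("reference_dye")
        for t, got in zip(prof.positions, prof.intensity):
            x = v.center[0] + t * np.cos(0.3)
            y = v.center[1] + t * np.sin(0.3)
            fx, fy = x / img.pixel_size - 0.5, y / img.pixel_size - 0.5
            i0, j0 = int(np.floor(fy)), int(np.floor(fx))
            dy, dx = fy - i0, fx - j0
            expected = (
                plane[i0, j0] * (1 - dx) * (1 - dy)
                + plane[i0, j0 + 1] * dx * (1 - dy)
                + plane[i0 + 1, j0] * (1 - dx) * dy
                + plane[i0 + 1, j0 + 1] * dx * dy
            )
            assert got == pytest.approx(expected, rel=1e-12)

    def test_profile_peaks_at_vesicle_membrane(self):
        # along a diameter the blurred ring peaks near ±radius
        scene = make_clean_scene(rho=1.0, radius=0.5)
        img = noiseless_image(scene, psf_sigma=0.1)
        v = scene.vesicles[0]
        prof = eq.extract_line_profile(img, "reference_dye", v.center, 0.0, 3.0)
        t_peak = abs(prof.positions[int(np.argmax(prof.intensity))])
        assert t_peak == pytest.approx(v.radius, abs=0.15)


class TestPmReference:
    def _pm_cross(self, scene):
        contour = scene.pm_contour
        i = 0
        point = contour[i]
        tangent = contour[i + 1] - contour[i - 1]
        normal = np.arctan2(tangent[0], -tangent[1])
        return tuple(point), float(normal)

    def test_matches_analytic_line_spread_peak(self):
        # straight-line source of density d: blurred cross-section peak is
        # d * px / (sqrt(2 pi) * sigma_px); the cell contour is locally
        # straight at this scale
        scene = make_clean_scene(n_vesicles=0)
        psf = 0.15
        img = noiseless_image(scene, psf_sigma=psf)
        point, normal = self._pm_cross(scene)
        ref = eq.pm_reference(img, "reference_dye", point, normal)
        d = scene.pm_density["reference_dye"]
        sigma_px = psf / img.pixel_size
        expected = d * img.pixel_size / (np.sqrt(2 * np.pi) * sigma_px)
        # sampling at pixel pitch can miss the true maximum by up to half a
        # pixel (a few percent at sigma = 1.5 px); it can never exceed it
        assert 0.90 * expected < ref < 1.01 * expected

    def test_two_sections_agree_on_uniform_membrane(self):
        scene = make_clean_scene(n_vesicles=0)
        img = noiseless_image(scene)
        contour = scene.pm_contour
        refs = []
        for i in (0, 180):
            tangent = contour[(i + 1) % 720] - contour[i - 1]
            angle = np.arctan2(tangent[0], -tangent[1])
            refs.append(
                eq.pm_reference(img, "reference_dye", tuple(contour[i]), float(angle))
            )
        assert refs[0] == pytest.approx(refs[1], rel=0.02)

    def test_zero_channel_raises_degenerate_reference(self):
        scene = make_clean_scene(n_vesicles=0)
        import dataclasses

        scene = dataclasses.replace(
            scene, pm_density={"protein": 0.0, "reference_dye": 2.0e4}
        )
        img = noiseless_image(scene)
        point, normal = self._pm_cross(scene)
        with pytest.raises(DegenerateReferenceError):
            eq.pm_reference(img, "protein", point, normal)

    def test_mean_mode_below_peak_mode(self):
        scene = make_clean_scene(n_vesicles=0)
        img = noiseless_image(scene)
        point, normal = self._pm_cross(scene)
        peak = eq.pm_reference(img, "reference_dye", point, normal, mode="peak")
        mean = eq.pm_reference(img, "reference_dye", point, normal, mode="mean")
        assert 0 < mean < peak


class TestSignalBackground:
    def test_ratio_arithmetic(self, uniform_image):
        img = uniform_image
        img.pixels[0, :50] = 40.0
        img.pixels[0, 50:] = 10.0
        m = eq.signal_background_ratio(
            img, "protein",
            eq.RectRoi((5.0, 2.0), 1.0, 1.0),
            eq.RectRoi((5.0, 8.0), 1.0, 1.0),
        )
        assert m.ratio == pytest.approx(4.0)

    def test_structure_on_cytosol_is_unity(self):
        scene = make_clean_scene(cytosol=2.7e3, n_vesicles=0)
        img = noiseless_image(scene)
        c = scene.cell_center
        # both discs sit 7 μm from the cell center: clear of the nucleus
        # (within 5.5 μm) and of the PM blur (3 μm from the contour)
        m = eq.signal_background_ratio(
            img, "protein",
            eq.DiscRoi((c[0] + 7.0, c[1]), 0.3),
            eq.DiscRoi((c[0], c[1] - 7.0), 0.3),
        )
        assert m.ratio == pytest.approx(1.0, abs=0.02)

    def test_zero_background_raises(self, uniform_image):
        uniform_image.pixels[:] = 0.0
        with pytest.raises(DegenerateReferenceError):
            eq.signal_background_ratio(
                uniform_image, "protein",
                eq.DiscRoi((5.0, 5.0), 0.3), eq.DiscRoi((2.0, 2.0), 0.3),
            )


class TestVesicleDensityRatio:
    def test_reported_arithmetic_example(self):
        # peak_norm 0.25 with bg 0.05 over reference 1.05 with bg 0.05
        profiles = {
            "protein": constant_profile(0.25),
            "reference_dye": constant_profile(1.05),
        }
        pm_refs = {"protein": 1.0, "reference_dye": 1.0}
        backgrounds = {"protein": 0.05, "reference_dye": 0.05}
        m = eq.vesicle_density_ratio(profiles, pm_refs, backgrounds)
        assert m.density_ratio == pytest.approx(0.20)

    def test_identical_profiles_give_unity(self):
        profiles = {
            "protein": constant_profile(0.8),
            "reference_dye": constant_profile(0.8),
        }
        m = eq.vesicle_density_ratio(
            profiles, {"protein": 1.0, "reference_dye": 1.0},
            {"protein": 0.1, "reference_dye": 0.1},
        )
        assert m.density_ratio == pytest.approx(1.0)

    def test_negative_protein_numerator_clips_to_zero(self):
        profiles = {
            "protein": constant_profile(0.02),
            "reference_dye": constant_profile(1.0),
        }
        m = eq.vesicle_density_ratio(
            profiles, {"protein": 1.0, "reference_dye": 1.0},
            {"protein": 0.05, "reference_dye": 0.0},
        )
        assert m.density_ratio == 0.0

    def test_nonpositive_reference_numerator_is_unmeasurable(self):
        profiles = {
            "protein": constant_profile(0.3),
            "reference_dye": constant_profile(0.1),
        }
        with pytest.raises(UnmeasurableVesicleError):
            eq.vesicle_density_ratio(
                profiles, {"protein": 1.0, "reference_dye": 1.0},
                {"protein": 0.0, "reference_dye": 0.2},
            )

    def test_noiseless_pipeline_recovers_truth_exactly(self):
        scene = make_clean_scene(rho=0.64, radius=0.4)
        img = noiseless_image(scene)
        row = eq.measure_cell(img)
        assert row["density_ratio"] == pytest.approx(0.64, rel=1e-9)

    def test_gain_invariance_of_single_channel(self):
        # multiplying one channel's raster by k > 0 cancels in D
        scene = make_clean_scene(rho=0.4, cytosol=2.7e3)
        imaging = eq.ImagingConfig.for_roles(tuple(scene.channels))
        img = eq.render_image(scene, imaging, seed=3)
        d0 = eq.measure_cell(img)["density_ratio"]
        scaled = eq.MultiChannelImage(
            pixels=img.pixels.astype(float).copy(), pixel_size=img.pixel_size,
            channel_roles=dict(img.channel_roles), scene_truth=img.scene_truth,
        )
        scaled.pixels[scaled.channel_roles["protein"]] *= 7.3
        d1 = eq.measure_cell(scaled)["density_ratio"]
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_monotone_in_ground_truth_density(self):
        rhos = [0.05, 0.2, 0.4, 0.64, 0.9]
        estimates = []
        for rho in rhos:
            scene = make_clean_scene(rho=rho)
            img = noiseless_image(scene)
            estimates.append(eq.measure_cell(img)["density_ratio"])
        assert np.all(np.diff(estimates) > 0)


class TestEnrichmentRatio:
    def test_threefold_receptor_profile(self):
        profiles = {
            "receptor": constant_profile(0.9),
            "reference_dye": constant_profile(0.3),
        }
        m = eq.enrichment_ratio(
            profiles, {"receptor": 1.0, "reference_dye": 1.0},
            {"receptor": 0.0, "reference_dye": 0.0},
        )
        assert m.density_ratio == pytest.approx(3.0)

    def test_receptor_at_background_gives_zero(self):
        profiles = {
            "receptor": constant_profile(0.05),
            "reference_dye": constant_profile(1.0),
        }
        m = eq.enrichment_ratio(
            profiles, {"receptor": 1.0, "reference_dye": 1.0},
            {"receptor": 0.05, "reference_dye": 0.0},
        )
        assert m.density_ratio == 0.0

    def test_noiseless_receptor_recovery(self):
        scene = make_clean_scene(
            rho=0.28, receptor_rho=3.0,
            channels=("protein", "reference_dye", "receptor"),
        )
        img = noiseless_image(scene)
        row = eq.measure_cell(img)
        assert row["enrichment_ratio"] == pytest.approx(3.0, rel=1e-9)


class TestSummarizeDensity:
    def test_t_quantile_example(self):
        s = eq.summarize_density([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        # t(0.975, 2) * sd / sqrt(3) = 4.3027 / sqrt(3)
        assert s.ci95_halfwidth == pytest.approx(2.484, abs=1e-3)
        assert s.n == 3

    def test_equal_values_have_zero_halfwidth(self):
        s = eq.summarize_density([0.5, 0.5, 0.5, 0.5])
        assert s.ci95_halfwidth == 0.0

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            eq.summarize_density([0.2])
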