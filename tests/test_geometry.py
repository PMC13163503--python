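import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscmap import geometry
from sscmap.geometry import (
    AngleMap,
    DarkReference,
    GeometryParams,
    HeightMap,
    HyperCube,
    WhiteReference,
    align_height_to_cube,
    angle_correct_intensity,
    combined_correct,
    compute_reflectance,
    correct_cube,
    height_correct_intensity,
    height_factor,
    interpolated_white,
    surface_angle,
)


def make_cube(values, wl=None, **kw):
    values = np.asarray(values, dtype=float)
    if wl is None:
        wl = np.arange(values.shape[2], dtype=float) + 1000.0
    return HyperCube(values=values, wavelengths=wl, **kw)


class TestTypes:
    def test_wavelengths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_cube(np.ones((2, 2, 3)), wl=np.array([3.0, 2.0, 1.0]))

    def test_band_index_nearest_and_out_of_range(self):
        cube = make_cube(np.ones((2, 2, 5)),
                         wl=np.array([1000.0, 1010, 1020, 1030, 1040]))
        assert cube.band_index(1012.0) == 1
        with pytest.raises(ValueError, match="outside"):
            cube.band_index(1200.0)

    def test_white_stack_heights_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            WhiteReference(values=np.ones((3, 2, 4)),
                           heights_mm=np.array([0.0, 4.0, 2.0]))

    def test_geometry_params_validation(self):
        with pytest.raises(ValueError):
            GeometryParams(H1_mm=-5.0)
        with pytest.raises(ValueError):
            GeometryParams(cos_floor=1.5)


class TestComputeReflectance:
    def test_identity_when_I_equals_W(self):
        white = WhiteReference(np.full((3, 4), 9000.0))
        dark = DarkReference(np.full((3, 4), 1000.0))
        cube = make_cube(np.full((2, 3, 4), 9000.0))
        out = compute_reflectance(cube, white, dark)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.kind == "reflectance"

    def test_zero_when_I_equals_D(self):
        white = WhiteReference(np.full((3, 4), 9000.0))
        dark = DarkReference(np.full((3, 4), 1000.0))
        cube = make_cube(np.full((2, 3, 4), 1000.0))
        np.testing.assert_allclose(
            compute_reflectance(cube, white, dark).values, 0.0
        )

    def test_half_reflectance_arithmetic(self):
        white = WhiteReference(np.full((1, 1), 9000.0))
        dark = DarkReference(np.full((1, 1), 1000.0))
        cube = make_cube(np.full((1, 1, 1), 5000.0))
        assert compute_reflectance(cube, white, dark).values[0, 0, 0] == 0.5

    def test_nonpositive_white_minus_dark_names_location(self):
        white = np.full((2, 3), 9000.0)
        white[1, 2] = 500.0
        dark = DarkReference(np.full((2, 3), 1000.0))
        cube = make_cube(np.full((2, 2, 3), 5000.0))
        with pytest.raises(ValueError, match="column 1, band 2"):
            compute_reflectance(cube, WhiteReference(white), dark)

    @settings(max_examples=25, deadline=None)
    @given(gain=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, gain):
        rng = np.random.default_rng(0)
        intensity = rng.uniform(2000, 8000, (2, 3, 4))
        white = rng.uniform(8500, 9500, (3, 4))
        dark = rng.uniform(900, 1100, (3, 4))
        base = compute_reflectance(
            make_cube(intensity), WhiteReference(white), DarkReference(dark)
        )
        scaled = compute_reflectance(
            make_cube(intensity * gain), WhiteReference(white * gain),
            DarkReference(dark * gain)
        )
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)


class TestHeightFactor:
    def test_panel_plane_identity(self):
        assert height_factor(0.0, GeometryParams()) == pytest.approx(1.0)

    def test_printed_closed_form_negative_height(self):
        # H1=100, H2=200, Hs=-10: (0.9)^2 * (0.95)^2 = 0.731025
        params = GeometryParams(H1_mm=100.0, H2_mm=200.0)
        assert height_factor(-10.0, params) == pytest.approx(0.731025)

    def test_strictly_increasing_in_height(self):
        params = GeometryParams()
        hs = np.linspace(-50.0, 60.0, 200)
        vals = height_factor(hs, params)
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_distance_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            height_factor(-150.0, GeometryParams(H1_mm=100.0))

    def test_height_sign_flag_negates(self):
        plus = height_factor(10.0, GeometryParams())
        flipped = height_factor(-10.0, GeometryParams(height_sign=-1.0))
        assert plus == pytest.approx(flipped)


class TestHeightCorrect:
    def test_zero_height_gives_dark_subtracted(self):
        dark = DarkReference(np.full((3, 4), 1000.0))
        cube = make_cube(np.full((2, 3, 4), 5000.0))
        height = HeightMap(np.zeros((2, 3)))
        out = height_correct_intensity(cube, dark, height, GeometryParams())
        np.testing.assert_allclose(out.values, 4000.0)
        assert out.dark_subtracted

    def test_single_pixel_composition(self):
        dark = DarkReference(np.full((3, 1), 1000.0))
        cube = make_cube(np.full((1, 3, 1), 5000.0))
        hvals = np.zeros((1, 3))
        hvals[0, 1] = -10.0
        out = height_correct_intensity(cube, dark, HeightMap(hvals),
                                       GeometryParams())
        assert out.values[0, 1, 0] == pytest.approx(4000.0 * 0.731025)
        assert out.values[0, 0, 0] == pytest.approx(4000.0)

    def test_phantom_column_bias_removed(self, clean_scene):
        # after height+angle correction all equal-reflectance flesh pixels agree
        params = clean_scene.geometry_params
        theta = surface_angle(clean_scene.height,
                              mode=clean_scene.config.angle_mode)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = combined_correct(clean_scene.cube, clean_scene.dark,
                                    clean_scene.height, theta, params)
        refl = compute_reflectance(corr, clean_scene.white, clean_scene.dark)
        # pixels on one SSC iso-row share identical true reflectance
        row = clean_scene.flesh_mask.shape[0] // 2
        sel = clean_scene.flesh_mask[row] & (theta.cos[row] >= 0.5)
        band = 10
        vals = refl.values[row, sel, band]
        assert np.nanvar(vals) < 1e-10


class TestInterpolatedWhite:
    @staticmethod
    def stack():
        heights = np.array([0.0, 2.0, 4.0, 6.0])
        vals = np.stack([np.full((3, 5), 9000.0 - 100.0 * h)
                         for h in heights])
        return WhiteReference(values=vals, heights_mm=heights)

    def test_knot_identity(self):
        stack = self.stack()
        np.testing.assert_allclose(interpolated_white(stack, 2.0),
                                   stack.values[1])

    def test_midpoint_mean(self):
        stack = self.stack()
        mid = interpolated_white(stack, 3.0)
        np.testing.assert_allclose(mid, (stack.values[1] + stack.values[2]) / 2)

    def test_matches_bruteforce_two_point_oracle(self, rng):
        heights = np.array([0.0, 2.0, 5.0, 9.0])
        vals = rng.uniform(8000, 10000, (4, 3, 6))
        stack = WhiteReference(values=vals, heights_mm=heights)
        for hs in rng.uniform(0.0, 9.0, 10):
            got = interpolated_white(stack, float(hs))
            k = np.searchsorted(heights, hs) - 1
            k = np.clip(k, 0, 2)
            f = (hs - heights[k]) / (heights[k + 1] - heights[k])
            expected = (1 - f) * vals[k] + f * vals[k + 1]
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_clamped_outside_range(self):
        stack = self.stack()
        np.testing.assert_allclose(interpolated_white(stack, -5.0),
                                   stack.values[0])
        np.testing.assert_allclose(interpolated_white(stack, 100.0),
                                   stack.values[-1])

    def test_requires_stack(self):
        single = WhiteReference(np.full((3, 5), 9000.0))
        with pytest.raises(ValueError, match="stack"):
            interpolated_white(single, 1.0)


class TestSurfaceAngle:
    def test_flat_map_zero(self):
        theta = surface_angle(HeightMap(np.zeros((4, 5))))
        np.testing.assert_allclose(theta.theta, 0.0)

    def test_unit_ramp_45_degrees(self):
        # 1 mm rise per 1 mm pixel along width -> 45 deg
        h = np.tile(np.arange(6, dtype=float), (4, 1))
        theta = surface_angle(HeightMap(h, pixel_pitch_mm=1.0))
        np.testing.assert_allclose(theta.theta[:, 1:-1], np.pi / 4, rtol=1e-12)

    def test_scan_direction_slope_invisible_in_width_mode(self):
        h = np.tile(np.arange(5, dtype=float)[:, None], (1, 6))
        width_only = surface_angle(HeightMap(h), mode="width")
        full = surface_angle(HeightMap(h), mode="full")
        np.testing.assert_allclose(width_only.theta, 0.0)
        assert np.all(full.theta[1:-1] > 0)

    def test_narrow_grid_errors(self):
        with pytest.raises(ValueError, match="width"):
            surface_angle(HeightMap(np.zeros((4, 2))))

    def test_pitch_scales_angle(self):
        h = np.tile(np.arange(6, dtype=float), (4, 1))
        fine = surface_angle(HeightMap(h, pixel_pitch_mm=2.0))
        np.testing.assert_allclose(fine.theta[:, 1:-1], np.arctan(0.5))


class TestAngleCorrect:
    def test_zero_angle_identity(self):
        dark = DarkReference(np.full((3, 4), 1000.0))
        cube = make_cube(np.full((2, 3, 4), 5000.0))
        out = angle_correct_intensity(cube, dark,
                                      AngleMap(np.zeros((2, 3))),
                                      GeometryParams())
        np.testing.assert_allclose(out.values, 4000.0)

    def test_sixty_degrees_doubles(self):
        dark = DarkReference(np.full((1, 1), 1000.0))
        cube = make_cube(np.full((1, 1, 1), 5000.0))
        out = angle_correct_intensity(cube, dark,
                                      AngleMap(np.full((1, 1), np.pi / 3)),
                                      GeometryParams())
        assert out.values[0, 0, 0] == pytest.approx(8000.0)

    def test_below_floor_masked_with_warning(self):
        dark = DarkReference(np.full((2, 1), 1000.0))
        cube = make_cube(np.full((1, 2, 1), 5000.0))
        theta = AngleMap(np.array([[0.0, 1.55]]))  # cos(1.55) ~ 0.02
        with pytest.warns(UserWarning, match="masked 1 pixels"):
            out = angle_correct_intensity(cube, dark, theta, GeometryParams())
        assert np.isnan(out.values[0, 1, 0])
        assert out.values[0, 0, 0] == pytest.approx(4000.0)

    def test_sphere_cap_cv_reduced(self, clean_scene):
        # corrected reflectance varies far less across the cap than uncorrected
        params = clean_scene.geometry_params
        theta = surface_angle(clean_scene.height,
                              mode=clean_scene.config.angle_mode)
        cap = clean_scene.flesh_mask & (theta.cos >= 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = correct_cube(clean_scene.cube, clean_scene.dark,
                                 clean_scene.white, clean_scene.height,
                                 params, "none")
            corr = correct_cube(clean_scene.cube, clean_scene.dark,
                                clean_scene.white, clean_scene.height,
                                params, "height_angle")
        row = clean_scene.flesh_mask.shape[0] // 2
        sel = cap[row]
        band = 5
        cv_plain = np.nanstd(plain.values[row, sel, band]) / np.nanmean(
            plain.values[row, sel, band])
        cv_corr = np.nanstd(corr.values[row, sel, band]) / np.nanmean(
            corr.values[row, sel, band])
        assert cv_corr <= 0.01 * cv_plain


class TestCombinedAndChain:
    def test_identity_when_flat(self, flat_scene):
        params = flat_scene.geometry_params
        theta = surface_angle(flat_scene.height)
        out = combined_correct(flat_scene.cube, flat_scene.dark,
                               flat_scene.height, theta, params)
        expected = flat_scene.cube.values - flat_scene.config.dark_level
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_equals_composition(self, clean_scene):
        params = clean_scene.geometry_params
        theta = surface_angle(clean_scene.height,
                              mode=clean_scene.config.angle_mode)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            combined = combined_correct(clean_scene.cube, clean_scene.dark,
                                        clean_scene.height, theta, params)
            staged = angle_correct_intensity(
                height_correct_intensity(clean_scene.cube, clean_scene.dark,
                                         clean_scene.height, params),
                clean_scene.dark, theta, params,
            )
        np.testing.assert_array_equal(combined.values, staged.values)

    def test_full_roundtrip_recovers_true_reflectance(self, clean_scene):
        params = clean_scene.geometry_params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refl = correct_cube(clean_scene.cube, clean_scene.dark,
                                clean_scene.white, clean_scene.height,
                                params, "height_angle")
        theta = surface_angle(clean_scene.height,
                              mode=clean_scene.config.angle_mode)
        ok = theta.cos >= 0.2
        err = np.abs(refl.values - clean_scene.true_reflectance) / np.abs(
            clean_scene.true_reflectance)
        assert np.nanmax(err[ok]) < 1e-6

    def test_all_modes_agree_on_flat_geometry(self, flat_scene):
        params = flat_scene.geometry_params
        outs = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mode in geometry.CORRECTION_MODES:
                outs[mode] = correct_cube(
                    flat_scene.cube, flat_scene.dark, flat_scene.white,
                    flat_scene.height, params, mode
                ).values
        for mode in ("height", "angle", "height_angle"):
            np.testing.assert_allclose(outs[mode], outs["none"], rtol=1e-12)

    def test_modes_commute_with_band_subsetting(self, clean_scene):
        params = clean_scene.geometry_params
        sel = np.arange(0, clean_scene.cube.n_bands, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = correct_cube(clean_scene.cube, clean_scene.dark,
                                clean_scene.white, clean_scene.height,
                                params, "height_angle").subset_bands(sel)
            sub_cube = clean_scene.cube.subset_bands(sel)
            sub_white = WhiteReference(clean_scene.white.values[:, sel])
            sub_dark = DarkReference(clean_scene.dark.values[:, sel])
            sub = correct_cube(sub_cube, sub_dark, sub_white,
                               clean_scene.height, params, "height_angle")
        np.testing.assert_allclose(full.values, sub.values, rtol=1e-12)

    def test_interpolated_white_variant_roundtrip(self, clean_scene):
        # build a white stack consistent with the inverse-square forward model
        cfg = clean_scene.config
        params = clean_scene.geometry_params
        heights = np.arange(0.0, 31.0, 2.0)
        dense = np.arange(0.0, 30.01, 0.01)
        w0 = clean_scene.white.values
        d = clean_scene.dark.values
        stack_vals = np.stack([
            d + (w0 - d) / geometry.height_factor(h, params) for h in heights
        ])
        stack = WhiteReference(values=stack_vals, heights_mm=heights)
        refl = geometry.height_correct_reflectance_interpolated(
            clean_scene.cube, clean_scene.dark, stack, clean_scene.height
        )
        assert refl.kind == "reflectance"
        # agreement with the closed-form variant is limited only by the
        # 2 mm linear interpolation of a smooth curve
        closed = correct_cube(clean_scene.cube, clean_scene.dark,
                              clean_scene.white, clean_scene.height,
                              params, "height")
        sel = clean_scene.flesh_mask
        ratio = refl.values[sel] / closed.values[sel]
        assert np.nanmax(np.abs(ratio - 1)) < 0.01


class TestAlignHeight:
    def test_identity_when_on_grid(self, flat_scene):
        out = align_height_to_cube(flat_scene.height, flat_scene.cube)
        assert out is flat_scene.height

    def test_constant_map_resampled_constant(self):
        cube = make_cube(np.zeros((10, 12, 3)))
        height = HeightMap(np.full((20, 24), 5.0), pixel_pitch_mm=0.5)
        out = align_height_to_cube(height, cube)
        assert out.values.shape == (10, 12)
        np.testing.assert_allclose(out.values, 5.0)

    def test_linear_ramp_matches_analytic_cell_centres(self):
        cube = make_cube(np.zeros((5, 5, 2)))
        src = np.tile(np.arange(10, dtype=float), (10, 1))
        out = align_height_to_cube(HeightMap(src), cube)
        # cell centre c of the coarse grid maps to (c+0.5)*2-0.5 on the fine
        expected = np.tile((np.arange(5) + 0.5) * 2 - 0.5, (5, 1))
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)
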