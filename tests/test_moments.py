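import math

import numpy as np
import pytest

from vertmorph import moments, phantom, segment
from vertmorph.stack_io import CalibratedStack


def _two_pixel_slice():
    """Two bone pixels of BMD 100 at (0.5, 0.5) and (1.5, 0.5) cm, spacing 1 cm."""
    img = np.zeros((1, 2))
    img[0, :] = 100.0
    return img, img > 0


class TestCentroid:
    def test_single_pixel_at_its_center(self):
        img = np.zeros((2, 2))
        img[0, 0] = 400.0
        assert moments.compute_centroid(img, img > 0, 1.0) == (0.5, 0.5)

    def test_equal_densities_give_midpoint(self):
        img = np.zeros((1, 2))
        img[0, 0] = img[0, 1] = 200.0  # centers x = 0.1, 0.3 at spacing 0.2
        xg, _ = moments.compute_centroid(img, img > 0, 0.2)
        assert xg == pytest.approx(0.2)

    def test_density_weighting(self):
        img = np.zeros((1, 2))
        img[0, 0], img[0, 1] = 100.0, 300.0
        xg, _ = moments.compute_centroid(img, img > 0, 0.2)
        assert xg == pytest.approx(0.25)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            moments.compute_centroid(np.zeros((3, 3)), np.zeros((3, 3), bool), 1.0)


class TestMomentAboutAxis:
    def test_two_pixel_hand_values(self):
        img, mask = _two_pixel_slice()
        cen = moments.compute_centroid(img, mask, 1.0)
        assert cen == (1.0, 0.5)
        vertical = moments.moment_about_axis(img, mask, cen, math.pi / 2, 1.0)
        assert vertical == pytest.approx(50.0)  # 2 * 0.25 * 100 * 1
        horizontal = moments.moment_about_axis(img, mask, cen, 0.0, 1.0)
        assert horizontal == pytest.approx(0.0, abs=1e-12)

    def test_collinear_pixels_give_zero(self):
        img = np.zeros((1, 5))
        img[0, :] = 123.0
        mask = img > 0
        cen = moments.compute_centroid(img, mask, 0.3)
        assert moments.moment_about_axis(img, mask, cen, 0.0, 0.3) == pytest.approx(
            0.0, abs=1e-12
        )


class TestMinimumMoment:
    def test_two_pixel_minimum_is_collinear_axis(self):
        img, mask = _two_pixel_slice()
        cen = moments.compute_centroid(img, mask, 1.0)
        imin, theta = moments.minimum_cross_sectional_moment(img, mask, cen, 1.0)
        assert imin == pytest.approx(0.0, abs=1e-12)
        assert theta == pytest.approx(0.0)
        assert moments.polar_moment(img, mask, cen, 1.0) == pytest.approx(50.0)

    def test_circular_annulus_is_isotropic(self):
        img, cen = phantom.annulus_map()
        mask = img > 0
        imin, theta = moments.minimum_cross_sectional_moment(img, mask, cen, 0.005)
        j = moments.polar_moment(img, mask, cen, 0.005)
        assert imin == pytest.approx(j / 2, rel=1e-9)
        assert theta == 0.0  # deterministic tie rule

    @pytest.mark.parametrize("seed", range(8))
    def test_eigen_solution_matches_theta_grid(self, seed, random_slice_factory):
        rng = np.random.default_rng(seed)
        img, mask = random_slice_factory(rng, n=30, n_pixels=rng.integers(5, 200))
        cen = moments.compute_centroid(img, mask, 0.01)
        imin, theta = moments.minimum_cross_sectional_moment(img, mask, cen, 0.01)
        thetas = np.linspace(0.0, math.pi, 3600, endpoint=False)
        grid = min(moments.moment_about_axis(img, mask, cen, t, 0.01) for t in thetas)
        assert imin == pytest.approx(grid, rel=1e-3, abs=1e-12)
        # the reported angle attains the minimum
        at_theta = moments.moment_about_axis(img, mask, cen, theta, 0.01)
        assert at_theta == pytest.approx(imin, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_perpendicular_axis_and_lower_bound(self, seed, random_slice_factory):
        rng = np.random.default_rng(100 + seed)
        img, mask = random_slice_factory(rng)
        cen = moments.compute_centroid(img, mask, 0.01)
        j = moments.polar_moment(img, mask, cen, 0.01)
        imin, _ = moments.minimum_cross_sectional_moment(img, mask, cen, 0.01)
        assert j >= 2 * imin - 1e-12 * j
        for theta in rng.uniform(0, math.pi, 20):
            pair = moments.moment_about_axis(
                img, mask, cen, theta, 0.01
            ) + moments.moment_about_axis(img, mask, cen, theta + math.pi / 2, 0.01)
            assert pair == pytest.approx(j, rel=1e-9)

    def test_polar_moment_of_annulus_closed_form(self):
        img, cen = phantom.annulus_map(0.40, 0.30, 300.0, 0.005)
        j = moments.polar_moment(img, img > 0, cen, 0.005)
        assert j == pytest.approx(300.0 * (math.pi / 2) * (0.40**4 - 0.30**4), rel=0.01)


def _uniform_stack(rho=400.0, areas_px=(200, 300), spacing=0.1, d=0.1):
    shape = (30, 30)
    slices, masks = [], []
    for n_px in areas_px:
        img = np.zeros(shape)
        img.ravel()[:n_px] = rho
        slices.append(img)
        masks.append(img > 0)
    stack = CalibratedStack(
        slices=np.stack(slices),
        pixel_spacing=spacing,
        slice_interval_d=d,
        vertebra_labels={"L2": (0, len(areas_px) - 1)},
    )
    return stack, masks


class TestBmdAndVolume:
    def test_volume_is_d_times_summed_areas(self):
        # S(1)=2 cm^2, S(2)=3 cm^2 at 0.1 cm spacing; d = 0.1 cm
        stack, masks = _uniform_stack()
        bmd, mineral, volume = moments.bmd_and_volume(stack, masks)
        assert volume == pytest.approx(0.5)

    def test_uniform_density_recovered_exactly_and_books_balance(self):
        stack, masks = _uniform_stack(rho=417.0)
        bmd, mineral, volume = moments.bmd_and_volume(stack, masks)
        assert bmd == pytest.approx(417.0, rel=1e-12)
        assert bmd * volume == pytest.approx(mineral, rel=1e-12)

    def test_all_slices_excluded_is_an_error(self):
        stack, _ = _uniform_stack()
        with pytest.raises(ValueError, match="excluded"):
            moments.bmd_and_volume(stack, [None, None])


class TestCorticalThickness:
    def _bm(self, img, spacing):
        mask = segment.segment_bone(img, 160.0)
        return segment.classify_cortical(mask, img, pixel_spacing=spacing)

    def test_annulus_thickness_within_half_pixel(self):
        img, _ = phantom.annulus_map(0.40, 0.30, 800.0, 0.005)
        bm = self._bm(img, 0.005)
        t = moments.slice_cortical_thickness(bm, 0.005)
        assert abs(t - 1.0) <= 0.5 * 0.005 * 10  # half a pixel, in mm

    def test_single_pixel_ring_reads_about_one_pixel(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 800.0
        img[6:14, 6:14] = 0.0  # 1-px-wide square ring
        bm = self._bm(img, 0.01)
        t = moments.slice_cortical_thickness(bm, 0.01)
        assert abs(t - 0.1) <= 0.1  # within one pixel (mm)

    def test_rotation_leaves_thickness_within_two_percent(self):
        kw = dict(pixel_spacing=0.005, grid_size=200)
        t0 = moments.slice_cortical_thickness(
            self._bm(phantom.render_cross_section(0.35, 0.28, 0.05, 850, 250, **kw), 0.005),
            0.005,
        )
        t1 = moments.slice_cortical_thickness(
            self._bm(
                phantom.render_cross_section(
                    0.35, 0.28, 0.05, 850, 250, rotation=math.radians(30), **kw
                ),
                0.005,
            ),
            0.005,
        )
        assert t1 == pytest.approx(t0, rel=0.02)

    def test_mean_requires_all_three_vertebrae(self):
        img, _ = phantom.annulus_map(0.40, 0.30, 800.0, 0.005)
        bm = self._bm(img, 0.005)
        with pytest.raises(ValueError, match="L4"):
            moments.mean_cortical_thickness({"L2": [bm], "L3": [bm]}, 0.005)


class TestVertebralDimensions:
    def _stack_with_widths(self, widths_px, spacing=0.05, d=0.1):
        shape = (40, 40)
        slices = []
        for w in widths_px:
            img = np.zeros(shape)
            img[15:25, 10 : 10 + w] = 500.0
            slices.append(img)
        stack = CalibratedStack(
            slices=np.stack(slices),
            pixel_spacing=spacing,
            slice_interval_d=d,
            vertebra_labels={"L2": (0, len(widths_px) - 1)},
        )
        masks = [s > 0 for s in stack.slices]
        return stack, masks

    def test_height_counts_labeled_slices(self):
        stack, masks = self._stack_with_widths([10] * 6)
        height, _ = moments.vertebral_dimensions(stack, masks, "L2")
        assert height == pytest.approx(6.0)  # 6 slices * 0.1 cm = 6 mm

    def test_constant_width_recovered_within_one_pixel(self):
        stack, masks = self._stack_with_widths([12] * 4)
        _, width = moments.vertebral_dimensions(stack, masks, "L2")
        assert abs(width - 12 * 0.05 * 10) <= 0.05 * 10

    def test_tapered_width_uses_intermediate_value(self):
        # superior 10 px = 5.0 mm, inferior 12 px = 6.0 mm -> 5.5 mm
        stack, masks = self._stack_with_widths([10, 11, 11, 12])
        _, width = moments.vertebral_dimensions(stack, masks, "L2")
        assert width == pytest.approx(5.5)

    def test_single_slice_vertebra_rejected(self):
        stack, masks = self._stack_with_widths([10])
        with pytest.raises(ValueError, match="single slice"):
            moments.vertebral_dimensions(stack, masks, "L2")


class TestVertebraAverage:
    def test_arithmetic_mean(self):
        assert moments.vertebra_average({"L2": 1.0, "L3": 2.0, "L4": 3.0}) == 2.0
        assert moments.vertebra_average({"L2": 0.9, "L3": 1.0, "L4": 1.4}) == pytest.approx(1.1)

    def test_identical_values_are_preserved(self):
        assert moments.vertebra_average(dict.fromkeys(("L2", "L3", "L4"), 7.3)) == 7.3

    def test_missing_vertebra_named_in_error(self):
        with pytest.raises(ValueError, match="L3"):
            moments.vertebra_average({"L2": 1.0, "L4": 3.0})


class TestInvariances:
    def test_translation_invariance_to_machine_precision(self):
        sp = 0.005
        kw = dict(pixel_spacing=sp, grid_size=200)
        a = phantom.render_cross_section(0.35, 0.28, 0.05, 850, 250, **kw)
        b = phantom.render_cross_section(
            0.35, 0.28, 0.05, 850, 250, center=(0.5 + 9 * sp, 0.5 - 13 * sp), **kw
        )
        out = []
        for img in (a, b):
            mask = img > 160
            cen = moments.compute_centroid(img, mask, sp)
            imin, _ = moments.minimum_cross_sectional_moment(img, mask, cen, sp)
            out.append((imin, moments.polar_moment(img, mask, cen, sp)))
        assert out[0][0] == pytest.approx(out[1][0], rel=1e-9)
        assert out[0][1] == pytest.approx(out[1][1], rel=1e-9)

    def test_physical_outputs_stable_under_pixel_spacing_change(self):
        results = {}
        for sp, n in ((0.005, 200), (0.01, 100)):
            img = phantom.render_cross_section(
                0.35, 0.28, 0.05, 850, 250, pixel_spacing=sp, grid_size=n
            )
            mask = img > 160
            cen = moments.compute_centroid(img, mask, sp)
            imin, _ = moments.minimum_cross_sectional_moment(img, mask, cen, sp)
            j = moments.polar_moment(img, mask, cen, sp)
            results[sp] = (imin, j)
        assert results[0.005][0] == pytest.approx(results[0.01][0], rel=0.01)
        assert results[0.005][1] == pytest.approx(results[0.01][1], rel=0.01)
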