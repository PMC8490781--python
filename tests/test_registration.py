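"""Registration: NCC shift estimation against the exhaustive oracle,
rotation search, the twirl warp's analytic geometry, and end-to-end
transform recovery on phantoms with known ground truth."""

import math

import numpy as np
import pytest

from tempsub import (
    Ellipse,
    ImageGrid,
    RegistrationConfig,
    ShiftEstimate,
    TwirlTransform,
    estimate_rotation,
    estimate_shift,
    generate_pair,
    register,
    twirl_warp,
)
from conftest import exhaustive_ncc_shift, small_spec

REG_CFG = RegistrationConfig(template_roi=(32, 32, 64, 64), search_radius=12)


class TestEstimateShift:
    def test_identity_images(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        est = estimate_shift(t1, t1, (32, 32, 64, 64), 12)
        assert (est.dtx, est.dty) == (0.0, 0.0)
        assert est.peak_ncc == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("shift", [(3, -2), (-5, 4), (0, 7), (10, 0)])
    def test_matches_exhaustive_oracle_on_phantoms(self, shift):
        t1, t2, _ = generate_pair(small_spec(global_shift=shift))
        est = estimate_shift(t1, t2, (32, 32, 64, 64), 12)
        oracle, _ = exhaustive_ncc_shift(t1.pixels, t2.pixels, (32, 32, 64, 64), 12)
        assert (est.dtx, est.dty) == oracle == shift

    def test_matches_oracle_on_random_32x32(self):
        """Exact integer agreement with the exhaustive-search oracle on
        arbitrary random rasters (not just clean phantoms)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = ImageGrid(rng.random((32, 32)) * 255)
            b = ImageGrid(rng.random((32, 32)) * 255)
            est = estimate_shift(a, b, (10, 10, 12, 12), 5)
            oracle, _ = exhaustive_ncc_shift(a.pixels, b.pixels, (10, 10, 12, 12), 5)
            assert (est.dtx, est.dty) == oracle

    def test_zero_variance_template_errors(self):
        img = ImageGrid(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="zero-variance.*ROI"):
            estimate_shift(img, img, (16, 16, 16, 16), 8)

    def test_roi_must_fit(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        with pytest.raises(ValueError, match="does not fit"):
            estimate_shift(t1, t1, (120, 120, 16, 16), 8)

    def test_subpixel_stays_close_to_integer_peak(self):
        t1, t2, _ = generate_pair(small_spec(global_shift=(4, -3)))
        est = estimate_shift(t1, t2, (32, 32, 64, 64), 12, subpixel=True)
        assert est.dtx == pytest.approx(4.0, abs=0.5)
        assert est.dty == pytest.approx(-3.0, abs=0.5)


class TestEstimateRotation:
    def test_identical_images_give_zero(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        grid = list(np.arange(-10.0, 11.0, 1.0))
        assert estimate_rotation(t1, t1, None, grid) == 0.0

    def test_recovers_phantom_rotation(self):
        t1, t2, truth = generate_pair(
            small_spec(misregistration="rotation", magnitude=5.0)
        )
        grid = list(np.arange(-10.0, 10.5, 0.5))
        est = estimate_rotation(t1, t2, None, grid)
        assert est == pytest.approx(truth.applied_rotation, abs=0.5)

    def test_single_candidate_grid(self, spec_growth):
        t1, t2, _ = generate_pair(spec_growth)
        assert estimate_rotation(t1, t2, None, [0.0]) == 0.0

    def test_empty_grid_rejected(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        with pytest.raises(ValueError):
            estimate_rotation(t1, t1, None, [])


class TestTwirlWarp:
    def test_zero_alpha_zero_shift_is_identity(self):
        rng = np.random.default_rng(3)
        img = ImageGrid(rng.random((64, 64)) * 255)
        out = twirl_warp(img, TwirlTransform((31.5, 31.5), 0.0, 20.0))
        assert np.abs(out.pixels - img.pixels).max() < 1e-9

    def test_pixels_beyond_rmax_unchanged(self):
        rng = np.random.default_rng(4)
        img = ImageGrid(rng.random((64, 64)) * 255)
        t = TwirlTransform((31.5, 31.5), math.pi / 4, 10.0)
        out = twirl_warp(img, t)
        yy, xx = np.mgrid[0:64, 0:64]
        outside = np.hypot(xx - 31.5, yy - 31.5) > 10.0
        np.testing.assert_array_equal(out.pixels[outside], img.pixels[outside])

    def test_half_radius_sources_at_half_alpha(self):
        """alpha = 90 deg: the output pixel on the +x axis at r = r_max/2
        samples the input at polar angle 45 deg, same radius."""
        r_max, r = 40.0, 20.0
        centre = (64.0, 64.0)
        src_angle = math.radians(45.0)
        sx = centre[0] + r * math.cos(src_angle)
        sy = centre[1] + r * math.sin(src_angle)
        img = np.zeros((129, 129))
        img[round(sy), round(sx)] = 100.0  # bright dot at the source point
        out = twirl_warp(
            ImageGrid(img), TwirlTransform(centre, math.pi / 2, r_max)
        )
        # response concentrates at the +x-axis point (centre + (r, 0))
        peak = np.unravel_index(np.argmax(out.pixels), out.pixels.shape)
        assert abs(peak[0] - centre[1]) <= 1 and abs(peak[1] - (centre[0] + r)) <= 1

    def test_continuity_across_rmax_boundary(self):
        """A smooth image warps without a discontinuity ring at r_max."""
        yy, xx = np.mgrid[0:128, 0:128]
        smooth = 200.0 * np.exp(-(((xx - 50) ** 2 + (yy - 70) ** 2) / (2 * 30.0**2)))
        out = twirl_warp(
            ImageGrid(smooth), TwirlTransform((63.5, 63.5), math.radians(20), 40.0)
        ).pixels
        gy, gx = np.gradient(out)
        gmag = np.hypot(gx, gy)
        r = np.hypot(xx - 63.5, yy - 63.5)
        ring = (r > 38.0) & (r < 42.0)
        interior = r <= 38.0
        assert gmag[ring].max() <= 2.0 * gmag[interior].max()

    def test_shift_applied_before_warp(self):
        rng = np.random.default_rng(5)
        img = ImageGrid(rng.random((64, 64)) * 255)
        t = TwirlTransform((31.5, 31.5), 0.0, 20.0, ShiftEstimate(3.0, -2.0, 1.0))
        out = twirl_warp(img, t)
        # undoing the shift moves content by (-3, +2)
        np.testing.assert_allclose(
            out.pixels[10:50, 10:50], img.pixels[8:48, 13:53], atol=1e-9
        )

    def test_invalid_rmax_rejected(self):
        with pytest.raises(ValueError):
            TwirlTransform((0.0, 0.0), 0.1, 0.0)


class TestRegister:
    def test_identical_images_identity_transform(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        res = register(t1, t1, REG_CFG)
        assert (res.transform.shift.dtx, res.transform.shift.dty) == (0.0, 0.0)
        assert res.transform.alpha == 0.0
        assert res.residual_rmse == pytest.approx(0.0, abs=1e-9)

    def test_recovers_shift_and_rotation(self):
        t1, t2, truth = generate_pair(
            small_spec(misregistration="rotation", magnitude=4.0, global_shift=(3, -2))
        )
        res = register(t1, t2, REG_CFG)
        t = res.transform
        assert (t.shift.dtx, t.shift.dty) == truth.applied_shift
        assert math.degrees(t.alpha) == pytest.approx(truth.applied_rotation, abs=1.0)
        pre = np.sqrt(np.mean((t1.pixels - t2.pixels) ** 2))
        assert res.residual_rmse < pre

    def test_growth_does_not_masquerade_as_motion(self):
        """Template away from the tumour: pure growth must leave the
        recovered transform at the identity."""
        spec = small_spec(
            tumour_t1=Ellipse((88.0, 40.0), (7.0, 5.0), 20.0, 180.0),
            tumour_t2=Ellipse((88.0, 40.0), (11.0, 8.0), 20.0, 180.0),
        )
        t1, t2, _ = generate_pair(spec)
        res = register(t1, t2, RegistrationConfig(template_roi=(40, 56, 48, 48),
                                                  search_radius=12))
        assert (res.transform.shift.dtx, res.transform.shift.dty) == (0.0, 0.0)
        assert res.transform.alpha == 0.0

    @pytest.mark.parametrize(
        "cls,mag", [("brain_expansion", 0.04), ("lateral_inclination", 0.05),
                    ("inclination", 0.05), ("rotation", 6.0)]
    )
    def test_registration_reduces_residual(self, cls, mag):
        t1, t2, _ = generate_pair(small_spec(misregistration=cls, magnitude=mag))
        res = register(t1, t2, REG_CFG)
        mask = t1.pixels > 0.05 * t1.pixels.max()
        pre = np.sqrt(np.mean((t1.pixels - t2.pixels)[mask] ** 2))
        assert res.residual_rmse <= pre + 1e-12

    def test_raster_mismatch_rejected(self, spec_identity):
        t1, _, _ = generate_pair(spec_identity)
        other = ImageGrid(np.zeros((64, 64)) + 1.0)
        with pytest.raises(ValueError, match="raster"):
            register(t1, other, REG_CFG)
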