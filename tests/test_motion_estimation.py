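"""Band-pass filter, B-spline FFD field, and FFD registration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from parmoco import (BandPassSpec, MotionVectorField, ReconGrid, ReconImage,
                     RegistrationConfig, bandpass, register)
from parmoco.fixtures import uniform_mvf
from parmoco.motion_estimation import control_grid_for, estimate_motion


def _sinusoid_image(grid, kx, ky):
    """Grid-periodic 2D sinusoid with integer wave numbers (no leakage);
    radial frequency is hypot(kx, ky) / n cycles/sample."""
    i = np.arange(grid.n)
    I, J = np.meshgrid(i, i, indexing="ij")
    phase = 2 * np.pi * (kx * J + ky * I) / grid.n
    return ReconImage(np.sin(phase), grid)


class TestBandPass:
    def test_constant_image_removed(self, small_grid):
        img = ReconImage(np.full((small_grid.n,) * 2, 3.7), small_grid)
        out = bandpass(img)
        assert np.abs(out.values).max() < 1e-10

    def test_inband_sinusoid_preserved(self, small_grid):
        # |k| = 13/128 ~ 0.2 pi rad/sample, mid-band
        img = _sinusoid_image(small_grid, 12, 5)
        out = bandpass(img)
        ratio = out.values.std() / img.values.std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_sinusoid_crushed(self, small_grid):
        img = _sinusoid_image(small_grid, 36, 16)  # ~0.62 pi rad/sample
        out = bandpass(img)
        assert out.values.std() < img.values.std() / 100.0

    def test_output_mean_is_zero(self, small_grid):
        rng = np.random.default_rng(0)
        img = ReconImage(rng.normal(size=(small_grid.n,) * 2), small_grid)
        out = bandpass(img)
        assert abs(out.values.mean()) < 1e-12

    def test_idempotent_up_to_taper(self, small_grid):
        # exactly idempotent wherever the mask is flat (pass or stop)...
        inband = _sinusoid_image(small_grid, 12, 5)
        once = bandpass(inband)
        twice = bandpass(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
        # ...and the taper regions bound the deviation for broadband input
        rng = np.random.default_rng(1)
        img = ReconImage(gaussian_filter(rng.normal(
            size=(small_grid.n,) * 2), 1.0), small_grid)
        once = bandpass(img)
        twice = bandpass(once)
        rel = np.sqrt(np.mean((twice.values - once.values) ** 2)
                      / np.mean(once.values ** 2))
        assert rel < 0.25

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandPassSpec(f_lo=0.3, f_hi=0.1)


class TestFFDField:
    def test_zero_controls_zero_displacement(self, small_grid):
        mvf = uniform_mvf((0.0, 0.0), small_grid.fov, 0.0, 1.0)
        pts = np.array([[0.0, 0.0], [30.0, -40.0], [-60.0, 10.0]])
        np.testing.assert_allclose(mvf.displace(pts), 0.0, atol=1e-14)

    def test_partition_of_unity_uniform_field(self, small_grid):
        mvf = uniform_mvf((2.5, -1.25), small_grid.fov, 0.0, 1.0)
        d = mvf.displacement_on_grid(small_grid)
        np.testing.assert_allclose(d[..., 0], 2.5, atol=1e-10)
        np.testing.assert_allclose(d[..., 1], -1.25, atol=1e-10)

    def test_single_bump_locality_and_weights(self, small_grid):
        spacing = 14.4
        origin, n_ctrl = control_grid_for(small_grid.fov, spacing)
        controls = np.zeros((n_ctrl, n_ctrl, 2))
        a, b = 6, 7
        controls[a, b, 0] = 1.0
        mvf = MotionVectorField(controls, spacing, origin, small_grid.fov,
                                0.0, 1.0)
        # at a grid-aligned point: tensor product of 1-D B-spline weights
        cx = origin + b * spacing
        cy = origin + a * spacing
        d = mvf.displace(np.array([[cx, cy]]))
        assert d[0, 0] == pytest.approx((2.0 / 3.0) ** 2)  # B3(0)^2
        assert d[0, 1] == 0.0
        # outside the 4x4-spacing support: exactly zero
        far = np.array([[cx + 2.5 * spacing, cy]])
        np.testing.assert_allclose(mvf.displace(far), 0.0, atol=1e-14)

    def test_displacement_cap_projection(self, small_grid):
        mvf = uniform_mvf((30.0, 0.0), small_grid.fov, 0.0, 1.0)
        d = mvf.displacement_on_grid(small_grid)
        assert np.hypot(d[..., 0], d[..., 1]).max() <= 14.3 + 1e-9

    def test_outside_points_clamped_with_warning(self, small_grid):
        mvf = uniform_mvf((1.0, 0.0), small_grid.fov, 0.0, 1.0)
        with pytest.warns(UserWarning, match="clamped"):
            d = mvf.displace(np.array([[1e4, 0.0]]))
        np.testing.assert_allclose(d, [[1.0, 0.0]], atol=1e-9)


def _structured_image(grid):
    """Band-passed rasterization of the static heart phantom."""
    from parmoco import preset
    from parmoco.phantom import ground_truth
    phantom = preset("static")
    img = ground_truth(phantom, 0.0, grid, supersample=2)
    return bandpass(img)


class TestRegister:
    def test_identity_registration_stays_put(self, small_grid):
        img = _structured_image(small_grid)
        mvf = register(img, img)
        d = mvf.displacement_on_grid(small_grid)
        assert np.hypot(d[..., 0], d[..., 1]).max() < 0.1 * small_grid.pixel_size

    def test_known_translation_recovered(self, full_grid):
        from parmoco import ReconImage
        rng = np.random.default_rng(4)
        img = bandpass(ReconImage(gaussian_filter(
            rng.normal(size=(full_grid.n,) * 2), 1.5), full_grid))
        px = full_grid.pixel_size
        iy, ix = np.meshgrid(np.arange(full_grid.n), np.arange(full_grid.n),
                             indexing="ij")
        # fixed(x) = moving(x + (5, 0) mm)
        fixed_vals = map_coordinates(img.values, [iy, ix + 5.0 / px],
                                     order=1, mode="nearest")
        fixed = img.copy_with(fixed_vals)
        mvf = register(fixed, img)
        d = mvf.displacement_on_grid(full_grid)
        gmag = np.hypot(*np.gradient(fixed.values))
        X, Y = full_grid.meshgrid()
        strong = (gmag > np.percentile(gmag, 90)) \
            & (np.hypot(X, Y) < 0.9 * full_grid.fov / 2)
        med = np.median(d[..., 0][strong])
        assert abs(med - 5.0) < 0.5
        assert abs(np.median(d[..., 1][strong])) < 0.5

    def test_synthetic_bspline_warp_recovered(self, full_grid):
        from parmoco import ReconImage
        rng = np.random.default_rng(31)
        img = bandpass(ReconImage(gaussian_filter(
            rng.normal(size=(full_grid.n,) * 2), 1.5), full_grid))
        spacing = 14.4
        origin, nc = control_grid_for(full_grid.fov, spacing)
        controls = gaussian_filter(rng.normal(0.0, 3.0, (nc, nc, 2)),
                                   (1.0, 1.0, 0.0))
        true = MotionVectorField(controls, spacing, origin, full_grid.fov,
                                 0.0, 1.0)
        d_true = true.displacement_on_grid(full_grid)
        mag = np.hypot(d_true[..., 0], d_true[..., 1])
        d_true *= 8.0 / mag.max()          # max warp 8 mm
        px = full_grid.pixel_size
        iy, ix = np.meshgrid(np.arange(full_grid.n), np.arange(full_grid.n),
                             indexing="ij")
        fixed_vals = map_coordinates(
            img.values, [iy + d_true[..., 1] / px, ix + d_true[..., 0] / px],
            order=1, mode="nearest")
        mvf = register(img.copy_with(fixed_vals), img)
        d_est = mvf.displacement_on_grid(full_grid)
        err = np.hypot(d_est[..., 0] - d_true[..., 0],
                       d_est[..., 1] - d_true[..., 1])
        X, Y = full_grid.meshgrid()
        central = np.hypot(X, Y) < 0.8 * full_grid.fov / 2
        assert err[central].mean() < px

    def test_objective_non_increasing(self, small_grid):
        img = _structured_image(small_grid)
        rolled = img.copy_with(np.roll(img.values, 3, axis=1))
        mvf = register(img, rolled)
        for hist in mvf.meta["loss_history"]:
            diffs = np.diff(hist)
            assert np.all(diffs <= 1e-12)

    def test_grid_mismatch_rejected(self, small_grid, full_grid):
        a = _structured_image(small_grid)
        b = _structured_image(full_grid)
        with pytest.raises(ValueError, match="grid"):
            register(a, b)


class TestEstimateMotion:
    def test_static_null_field(self, small_geometry, small_grid):
        from parmoco import (forward_project, preset, ramp_filter, rebin,
                             reconstruct_par, select_gating_window)
        from parmoco.projector import ScanTimeline
        phantom = preset("static")
        tl = ScanTimeline.for_scan(small_geometry, 2.0)
        sino = forward_project(phantom, small_geometry, tl)
        w = select_gating_window(tl, phantom.ecg, 0.35, small_geometry,
                                 cycle_index=0)
        filt = ramp_filter(rebin(sino, w))
        pa = reconstruct_par(filt, small_grid, "first")
        pb = reconstruct_par(filt, small_grid, "last")
        mvf = estimate_motion(pa, pb)
        assert mvf.t_start == pytest.approx(pa.center_time)
        assert mvf.t_end == pytest.approx(pb.center_time)
        d = mvf.displacement_on_grid(small_grid)
        mag = np.hypot(d[..., 0], d[..., 1])
        assert np.percentile(mag, 99) < 0.5

    def test_swapping_pars_negates_field(self, moving_case_80bpm):
        """Approximate inverse consistency of the registration."""
        from parmoco import ramp_filter, rebin, reconstruct_par, \
            select_gating_window
        case = moving_case_80bpm
        sino = case["sino"]
        w = select_gating_window(sino.timeline, case["phantom"].ecg,
                                 case["phase"], sino.geometry, cycle_index=1)
        filt = ramp_filter(rebin(sino, w))
        grid = case["grid"]
        pa = reconstruct_par(filt, grid, "first")
        pb = reconstruct_par(filt, grid, "last")
        from parmoco.motion_estimation import register, bandpass
        fwd = estimate_motion(pa, pb).displacement_on_grid(grid)
        bwd = register(bandpass(pb.image),
                       bandpass(pa.image)).displacement_on_grid(grid)
        X, Y = grid.meshgrid()
        heart = np.hypot(X - 12.0, Y + 4.0) < 55.0
        resid = np.hypot(fwd[..., 0] + bwd[..., 0],
                         fwd[..., 1] + bwd[..., 1])
        scale = np.hypot(fwd[..., 0], fwd[..., 1])[heart].mean()
        assert resid[heart].mean() < max(0.5 * scale, 1.0)
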