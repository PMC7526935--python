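"""Gating, rebinning, filtering, weighting, FBP and PAR reconstruction."""

import numpy as np
import pytest

from parmoco import (ReconGrid, ScanTimeline, SystemGeometry, backproject,
                     fbp_reconstruct, forward_project, ramp_filter, rebin,
                     reconstruct_par, redundancy_weights,
                     select_gating_window)
from parmoco.motion_estimation import bandpass
from parmoco.phantom import DynamicPhantom, ECGModel, static_primitive
from parmoco.fixtures import gated_timeline


def _static_disk_scan(geometry, mu=0.02, center=(15.0, -10.0), r=30.0,
                      n_rotations=1.2):
    p = DynamicPhantom([static_primitive("d", "disk", mu, center=center,
                                         semi_axes=(r, r))], ECGModel(60))
    tl = ScanTimeline.for_scan(geometry, n_rotations)
    return p, forward_project(p, geometry, tl)


class TestGatingWindow:
    def test_width_is_pi_plus_twice_fan(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        assert w.width == pytest.approx(np.pi + 2 * np.deg2rad(52.0))
        assert np.rad2deg(w.width) == pytest.approx(284.0)
        # 0.25 s rotation -> window duration ~ (284/360)*0.25 s
        dur = w.n_views * small_geometry.dt_view
        assert dur == pytest.approx(284.0 / 360.0 * 0.25, rel=0.01)

    def test_target_at_r_peak(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry, n_rotations=2.0)
        ecg = ECGModel(240.0, t0_rpeak=0.05)  # short cycles fit the scan
        w = select_gating_window(sino.timeline, ecg, 0.0, small_geometry,
                                 cycle_index=1)
        assert w.target_time == pytest.approx(0.05 + ecg.period)

    def test_window_exceeding_scan_rejected(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry, n_rotations=0.5)
        with pytest.raises(ValueError, match="exceeds|window"):
            select_gating_window(sino.timeline, p.ecg, 0.0, small_geometry,
                                 cycle_index=0)


class TestRebin:
    def test_constant_sinogram_stays_constant(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        sino.values[:] = 1.0
        ps = rebin(sino, w)
        assert ps.valid.all()
        np.testing.assert_allclose(ps.values, 1.0, atol=1e-9)

    def test_centered_disk_matches_parallel_closed_form(self):
        geo = SystemGeometry()     # full 736-channel sampling
        mu, r = 0.02, 30.0
        p, sino = _static_disk_scan(geo, mu=mu, center=(0.0, 0.0), r=r)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, geo,
                                 cycle_index=0)
        ps = rebin(sino, w)
        s = ps.radial_positions
        expected = 2.0 * mu * np.sqrt(np.clip(r ** 2 - s ** 2, 0, None))
        rms = np.sqrt(np.mean((ps.values - expected[None, :]) ** 2))
        assert rms < 0.01 * expected.max()

    def test_parallel_span_is_short_scan(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        assert ps.span == pytest.approx(np.pi + small_geometry.fan_rad,
                                        abs=2 * ps.dtheta)

    def test_s_zero_column_matches_central_fan_channel(self):
        geo = SystemGeometry(n_channels=257, views_per_rotation=360)
        p, sino = _static_disk_scan(geo, center=(20.0, 5.0), r=25.0)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, geo, cycle_index=0)
        ps = rebin(sino, w, n_radial=257)   # odd -> exact s=0 column
        j = 128
        assert abs(ps.radial_positions[j]) < 1e-9
        # s=0 -> gamma=0 -> beta=theta: compare to central fan channel
        i_b = np.round((ps.par_angles - sino.timeline.view_angles[w.start_index])
                       / geo.dbeta).astype(int) + w.start_index
        fan_central = sino.values[i_b, 128]
        np.testing.assert_allclose(ps.values[:, j], fan_central, atol=1e-6)


class TestRampFilterAndWeights:
    def test_zero_row_stays_zero(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        ps.values[:] = 0.0
        assert not ramp_filter(ps).values.any()

    def test_dc_suppressed(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        ps.values[:] = 1.0
        filtered = ramp_filter(ps)
        # the truncated discrete ramp leaves a small residual DC; it must
        # stay far below the kernel's peak response
        interior = filtered.values[:, 100:-100]
        assert np.abs(interior.mean()) < 1e-2 * np.abs(filtered.values).max()

    def test_conjugate_weights_sum_to_one(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        wts = redundancy_weights(ps)
        n_pi = int(round(np.pi / ps.dtheta))
        n_par = ps.values.shape[0]
        for i in range(n_par - n_pi):
            np.testing.assert_allclose(wts[i] + wts[i + n_pi][::-1], 1.0,
                                       atol=1e-12)
        core = wts[n_par - n_pi:n_pi]
        np.testing.assert_array_equal(core, 1.0)

    def test_span_below_pi_rejected(self, small_geometry):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        import dataclasses
        short = ps.copy_with(ps.values[:100])
        short.par_angles = ps.par_angles[:100]
        short.row_times = ps.row_times[:100]
        short.valid = ps.valid[:100]
        with pytest.raises(ValueError, match="span|insufficient"):
            redundancy_weights(short)


class TestBackprojectAndFBP:
    def test_zero_sinogram_zero_image(self, small_geometry, small_grid):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        ps = rebin(sino, w)
        ps.values[:] = 0.0
        img = backproject(ps, np.ones_like(ps.values), small_grid)
        assert not img.values.any()

    def test_fbp_recovers_mu_within_two_percent(self, small_geometry,
                                                small_grid):
        mu, r, c = 0.02, 30.0, (15.0, -10.0)
        p, sino = _static_disk_scan(small_geometry, mu=mu, center=c, r=r)
        img = fbp_reconstruct(sino, p.ecg, 0.1, small_grid, cycle_index=0)
        X, Y = small_grid.meshgrid()
        inside = np.hypot(X - c[0], Y - c[1]) < 0.8 * r
        assert img.values[inside].mean() == pytest.approx(mu, rel=0.02)

    def test_point_symmetric_phantom_gives_symmetric_image(self,
                                                           small_geometry,
                                                           small_grid):
        p, sino = _static_disk_scan(small_geometry, center=(0.0, 0.0), r=40.0)
        img = fbp_reconstruct(sino, p.ecg, 0.1, small_grid, cycle_index=0)
        flipped = img.values[::-1, ::-1]
        scale = np.abs(img.values).max()
        assert np.abs(img.values - flipped).max() < 0.02 * scale

    def test_linearity_in_mu(self, small_geometry, small_grid):
        p1, s1 = _static_disk_scan(small_geometry, mu=0.02)
        p2, s2 = _static_disk_scan(small_geometry, mu=0.04)
        i1 = fbp_reconstruct(s1, p1.ecg, 0.1, small_grid, cycle_index=0)
        i2 = fbp_reconstruct(s2, p2.ecg, 0.1, small_grid, cycle_index=0)
        np.testing.assert_allclose(i2.values, 2.0 * i1.values, atol=1e-10)

    def test_three_disk_phantom_ssim_against_truth(self, full_grid):
        from skimage.metrics import structural_similarity
        from parmoco.phantom import ground_truth
        geo = SystemGeometry()
        prims = [static_primitive(f"d{k}", "disk", mu, center=c,
                                  semi_axes=(r, r))
                 for k, (mu, c, r) in enumerate([
                     (0.022, (-40.0, 10.0), 25.0),
                     (0.026, (35.0, 30.0), 15.0),
                     (0.030, (10.0, -45.0), 8.0)])]
        p = DynamicPhantom(prims, ECGModel(60))
        tl = ScanTimeline.for_scan(geo, 1.2)
        sino = forward_project(p, geo, tl)
        img = fbp_reconstruct(sino, p.ecg, 0.1, full_grid, cycle_index=0)
        gt = ground_truth(p, img.target_time, full_grid)
        dr = float(gt.values.max() - gt.values.min())
        assert structural_similarity(img.values, gt.values,
                                     data_range=dr) > 0.95


@pytest.fixture(scope="module")
def par_pair(small_geometry, small_grid):
    p, sino = _static_disk_scan(small_geometry, center=(20.0, 15.0), r=25.0)
    w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                             cycle_index=0)
    filt = ramp_filter(rebin(sino, w))
    return (reconstruct_par(filt, small_grid, "first"),
            reconstruct_par(filt, small_grid, "last"))


class TestPAR:
    def test_span_is_fan_angle(self, par_pair, small_geometry):
        pa, pb = par_pair
        assert 2 * pa.angular_halfwidth == pytest.approx(
            small_geometry.fan_rad, abs=2 * small_geometry.dbeta)

    def test_conjugate_centers_and_times(self, par_pair, small_geometry):
        pa, pb = par_pair
        assert pb.angular_center - pa.angular_center == pytest.approx(
            np.pi, abs=1e-9)
        assert pb.center_time - pa.center_time == pytest.approx(
            small_geometry.rotation_time / 2.0, abs=1e-9)

    def test_static_conjugate_pars_agree_after_bandpass(self, par_pair,
                                                        small_grid):
        pa, pb = par_pair
        fa = bandpass(pa.image).values
        fb = bandpass(pb.image).values
        X, Y = small_grid.meshgrid()
        m = np.hypot(X, Y) < 0.95 * small_grid.fov / 2
        rel = np.sqrt(np.mean((fa - fb)[m] ** 2) / np.mean(fa[m] ** 2))
        assert rel < 0.01

    def test_oversized_par_span_rejected(self, small_geometry, small_grid):
        p, sino = _static_disk_scan(small_geometry)
        w = select_gating_window(sino.timeline, p.ecg, 0.1, small_geometry,
                                 cycle_index=0)
        filt = ramp_filter(rebin(sino, w))
        with pytest.raises(ValueError, match="span|window"):
            reconstruct_par(filt, small_grid, "first", par_angle=2 * np.pi)
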