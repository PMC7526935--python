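"""Reproducible end-to-end study fixtures.

This module wires the whole pipeline into the reference evaluation
protocol: simulate a beating phantom at heart rates 60/80/100 bpm,
reconstruct at the R-R 30% and 70% phases with plain short-scan FBP and
with motion compensation, and score three coronary-artery ROIs per case
with MSSIM plus per-ROI RMSE against the supersampled static ground
truth — 18 paired comparisons in total.  It also generates the
3-preset x 3-heart-rate x 2-phase regression scan suite with a JSON
manifest.

All computations are deterministic; ``seed`` only matters when photon
noise is explicitly requested.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .core import ReconGrid, ReconImage
from .metrics import LineProfile, ROISpec, mssim, paired_compare, rmse
from .motion_compensation import mc_backproject, sculli_reconstruct
from .motion_estimation import (BandPassSpec, MotionVectorField,
                                RegistrationConfig, control_grid_for)
from .phantom import (DynamicPhantom, ECGModel, ground_truth, preset,
                      static_primitive, TimeVaryingPrimitive)
from .projector import (FanSinogram, ScanTimeline, SystemGeometry,
                        add_noise, forward_project)
from .rebin_fbp import (fbp_reconstruct, ramp_filter, rebin,
                        redundancy_weights, select_gating_window)

HEART_RATES = (60.0, 80.0, 100.0)
PHASES = (0.3, 0.7)
PRESETS = ("xcat_like", "mocomo_like", "alpha_like")


def gated_timeline(geometry: SystemGeometry, ecg: ECGModel,
                   target_phase: float, cycle_index: int = 1,
                   margin_views: int = 24) -> ScanTimeline:
    """Timeline covering just the gating window of one phase (plus margin).

    Keeps simulation cost proportional to the reconstruction, not the
    whole multi-cycle scan; angles/times remain on the absolute scan
    lattice so gating stays consistent.
    """
    width = np.pi + 2.0 * geometry.fan_rad
    n_win = int(round(width / geometry.dbeta))
    t_target = ecg.time_at_phase(target_phase, cycle_index)
    c = int(round(t_target / geometry.dt_view))
    i0 = max(0, c - n_win // 2 - margin_views)
    i1 = c + n_win // 2 + margin_views
    k = np.arange(i0, i1 + 1)
    return ScanTimeline(view_angles=k * geometry.dbeta,
                        view_times=k * geometry.dt_view)


def artery_rois(phantom: DynamicPhantom, t: float,
                half_extent: float = 10.0) -> list[ROISpec]:
    """ROIs centered on the three artery disks frozen at time ``t``."""
    rois = []
    for fp in phantom.snapshot(t):
        if fp.name in ("rca", "lad", "lcx"):
            rois.append(ROISpec(center=fp.center, half_extent=half_extent,
                                label=fp.name))
    if not rois:
        raise ValueError("phantom has no artery primitives")
    return rois


def wall_profile_line(phantom: DynamicPhantom, n_samples: int = 60,
                      margin: float = 0.8) -> LineProfile:
    """Line inside the left myocardial-wall band at *every* phase.

    HU along it is constant in truth (uniform wall), so any pooled
    variation across reconstructed phases is artifact, mirroring the
    HU-stability measurement on a uniform wall region.
    """
    outer, inner = [], []
    for ph in np.linspace(0.0, 1.0, 21):
        frozen = {fp.name: fp for fp in phantom.snapshot_at_phase(ph)}
        wall = frozen["wall"]
        cx, cy = wall.center
        outer.append(cx - wall.semi_axes[0])
        inner.append(cx - wall.inner_semi_axes[0])
    x0 = max(outer) + margin   # innermost position of the outer edge
    x1 = min(inner) - margin   # outermost position of the inner edge
    if x1 - x0 < 2.0:
        raise ValueError("wall band too thin for a stable profile line")
    return LineProfile(start=(x0, cy), stop=(x1, cy), n_samples=n_samples)


def run_case(heart_rate: float, phase: float, preset_name: str = "xcat_like",
             grid_n: int = 256, fov: float = 250.0,
             geometry: SystemGeometry | None = None,
             reg: RegistrationConfig | None = None,
             band: BandPassSpec | None = None,
             cycle_index: int = 1, preset_options: dict | None = None) -> dict:
    """Simulate one case and reconstruct it with FBP and motion correction.

    Returns ground truth, both reconstructions, the phantom and the
    target time.
    """
    if geometry is None:
        geometry = SystemGeometry()
    phantom = preset(preset_name, heart_rate=heart_rate,
                     **(preset_options or {}))
    grid = ReconGrid(n=grid_n, pixel_size=fov / grid_n)
    timeline = gated_timeline(geometry, phantom.ecg, phase, cycle_index)
    sino = forward_project(phantom, geometry, timeline)
    t_target = phantom.ecg.time_at_phase(phase, cycle_index)
    gt = ground_truth(phantom, t_target, grid)
    fbp = fbp_reconstruct(sino, phantom.ecg, phase, grid,
                          cycle_index=cycle_index)
    sculli = sculli_reconstruct(sino, phantom.ecg, phase, grid,
                                cycle_index=cycle_index, band=band, reg=reg)
    return {"phantom": phantom, "grid": grid, "sino": sino, "gt": gt,
            "fbp": fbp, "sculli": sculli, "target_time": t_target,
            "heart_rate": heart_rate, "phase": phase}


def evaluation_suite(heart_rates=HEART_RATES, phases=PHASES, grid_n: int = 256,
                     roi_half_extent: float = 10.0,
                     reg: RegistrationConfig | None = None) -> dict:
    """The full ROI x heart-rate x phase paired evaluation.

    Returns per-case records (one per ROI) and summary statistics:
    suite-mean MSSIM/RMSE for each method and one-sided paired t-test
    p-values (alternative: motion correction better).
    """
    records = []
    for hr in heart_rates:
        for ph in phases:
            case = run_case(hr, ph, grid_n=grid_n, reg=reg)
            rois = artery_rois(case["phantom"], case["target_time"],
                               roi_half_extent)
            for roi in rois:
                m = roi.mask(case["gt"])
                records.append({
                    "heart_rate": hr, "phase": ph, "roi": roi.label,
                    "mssim_fbp": mssim(case["fbp"], case["gt"], roi),
                    "mssim_sculli": mssim(case["sculli"], case["gt"], roi),
                    "rmse_fbp": rmse(case["fbp"], case["gt"], m),
                    "rmse_sculli": rmse(case["sculli"], case["gt"], m),
                })
    ms_f = np.array([r["mssim_fbp"] for r in records])
    ms_s = np.array([r["mssim_sculli"] for r in records])
    rm_f = np.array([r["rmse_fbp"] for r in records])
    rm_s = np.array([r["rmse_sculli"] for r in records])
    summary = {
        "n_cases": len(records),
        "mean_mssim_fbp": float(ms_f.mean()),
        "mean_mssim_sculli": float(ms_s.mean()),
        "mean_rmse_fbp": float(rm_f.mean()),
        "mean_rmse_sculli": float(rm_s.mean()),
        "rmse_improved_cases": int(np.sum(rm_s < rm_f)),
        "p_mssim": paired_compare(ms_f, ms_s, alternative="less"),
        "p_rmse": paired_compare(rm_s, rm_f, alternative="less"),
    }
    return {"records": records, "summary": summary}


def profile_stability_case(heart_rate: float = 80.0, n_phases: int = 5,
                           grid_n: int = 256,
                           reg: RegistrationConfig | None = None) -> dict:
    """FBP vs motion-corrected HU stability on a wall line across phases.

    Phases are spread over the moving part of the cycle around the jerk
    between the systolic and diastolic rest windows.
    """
    from .metrics import profile_stability

    geometry = SystemGeometry()
    phantom = preset("xcat_like", heart_rate=heart_rate)
    grid = ReconGrid(n=grid_n, pixel_size=250.0 / grid_n)
    phases = np.linspace(0.35, 0.75, n_phases)
    fbps, scullis = [], []
    for ph in phases:
        timeline = gated_timeline(geometry, phantom.ecg, ph, 1)
        sino = forward_project(phantom, geometry, timeline)
        fbps.append(fbp_reconstruct(sino, phantom.ecg, ph, grid, cycle_index=1))
        scullis.append(sculli_reconstruct(sino, phantom.ecg, ph, grid,
                                          cycle_index=1, reg=reg))
    line = wall_profile_line(phantom)
    std_fbp, prof_fbp = profile_stability(fbps, line)
    std_sculli, prof_sculli = profile_stability(scullis, line)
    return {"phases": phases, "std_fbp": std_fbp, "std_sculli": std_sculli,
            "profiles_fbp": prof_fbp, "profiles_sculli": prof_sculli}


# --------------------------------------------------------------------------
# Known-motion oracle
# --------------------------------------------------------------------------

def translating_phantom(velocity=(40.0, -16.0), heart_rate: float = 60.0
                        ) -> DynamicPhantom:
    """A rigid group of structures translating linearly in time.

    ``velocity`` is in mm per cardiac cycle; within one cycle the
    trajectory is exactly linear in t, so the linear motion model is
    exact and compensation with the true field must recover the static
    image.
    """
    v = np.asarray(velocity, float)

    def mover(base):
        def f(phase):
            return tuple(np.asarray(base, float) + v * phase)
        return f

    prims = [
        TimeVaryingPrimitive(name="blob", shape="disk", mu=0.024,
                             center=mover((-15.0, -8.0)),
                             semi_axes=lambda ph: (30.0, 30.0)),
        TimeVaryingPrimitive(name="core", shape="ellipse", mu=0.030,
                             center=mover((-20.0, -12.0)),
                             semi_axes=lambda ph: (8.0, 5.0), host="blob"),
        TimeVaryingPrimitive(name="dot", shape="disk", mu=0.034,
                             center=mover((-2.0, 2.0)),
                             semi_axes=lambda ph: (2.5, 2.5), host="blob"),
    ]
    return DynamicPhantom(primitives=prims,
                          ecg=ECGModel(heart_rate=heart_rate),
                          fov_extent=250.0)


def uniform_mvf(displacement, extent: float, t_start: float, t_end: float,
                spacing: float = 3.6,
                cap: float | None = None) -> MotionVectorField:
    """Spatially uniform B-spline field (partition of unity makes the
    evaluated displacement exactly ``displacement`` everywhere)."""
    origin, n_ctrl = control_grid_for(extent, spacing)
    controls = np.broadcast_to(np.asarray(displacement, float),
                               (n_ctrl, n_ctrl, 2)).copy()
    kwargs = {} if cap is None else {"displacement_cap": cap}
    return MotionVectorField(controls=controls, spacing=spacing, origin=origin,
                             extent=extent, t_start=t_start, t_end=t_end,
                             **kwargs)


def known_motion_case(grid_n: int = 256, velocity=(40.0, -16.0),
                      phase: float = 0.3) -> dict:
    """Compensate exactly linear translation with the TRUE field."""
    geometry = SystemGeometry()
    phantom = translating_phantom(velocity=velocity)
    grid = ReconGrid(n=grid_n, pixel_size=250.0 / grid_n)
    timeline = gated_timeline(geometry, phantom.ecg, phase, 0)
    sino = forward_project(phantom, geometry, timeline)
    window = select_gating_window(timeline, phantom.ecg, phase, geometry,
                                  cycle_index=0)
    filtered = ramp_filter(rebin(sino, window))
    weights = redundancy_weights(filtered)
    from .rebin_fbp import backproject, reconstruct_par
    par_a = reconstruct_par(filtered, grid, "first")
    par_b = reconstruct_par(filtered, grid, "last")
    dt = par_b.center_time - par_a.center_time
    v_per_s = np.asarray(velocity, float) / phantom.ecg.period
    true_d = v_per_s * dt
    mvf = uniform_mvf(true_d, grid.fov, par_a.center_time, par_b.center_time)
    fbp = backproject(filtered, weights, grid)
    mc = mc_backproject(filtered, weights, mvf, grid)
    t_mid = 0.5 * (par_a.center_time + par_b.center_time)
    gt = ground_truth(phantom, t_mid, grid)
    return {"gt": gt, "fbp": fbp, "mc": mc, "mvf": mvf, "grid": grid,
            "true_displacement": true_d}


# --------------------------------------------------------------------------
# Regression scan suite
# --------------------------------------------------------------------------

def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def make_fixtures(outdir: str | Path, seed: int = 0, grid_n: int = 128,
                  views_per_rotation: int = 360, n_channels: int = 368,
                  photons_per_ray: float | None = None) -> dict:
    """Generate the 3-preset x 3-heart-rate x 2-phase regression suite.

    Writes one scan per (preset, heart rate), one ground-truth NIfTI per
    case, and a manifest with checksums.  Deterministic for a fixed
    seed (the seed only enters if photon noise is enabled).
    """
    from .io import RunConfig, write_nifti, write_scan_h5

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = SystemGeometry(views_per_rotation=views_per_rotation,
                              n_channels=n_channels)
    grid = ReconGrid(n=grid_n, pixel_size=250.0 / grid_n)
    cases = []
    rng_seed = int(seed)
    for preset_name in PRESETS:
        for hr in HEART_RATES:
            phantom = preset(preset_name, heart_rate=hr)
            # one scan covering both target phases in cycle 1
            width_t = (np.pi + 2 * geometry.fan_rad) / (2 * np.pi) \
                * geometry.rotation_time
            n_rot = float(np.ceil((2.0 * phantom.ecg.period + width_t)
                                  / geometry.rotation_time) + 1)
            timeline = ScanTimeline.for_scan(geometry, n_rotations=n_rot)
            sino = forward_project(phantom, geometry, timeline)
            if photons_per_ray:
                sino = add_noise(sino, photons_per_ray, rng_seed)
                rng_seed += 1
            scan_name = f"scan_{preset_name}_{int(hr)}bpm.h5"
            write_scan_h5(outdir / scan_name, sino, phantom.ecg)
            for ph in PHASES:
                t_target = phantom.ecg.time_at_phase(ph, 1)
                window = select_gating_window(timeline, phantom.ecg, ph,
                                              geometry, cycle_index=1)
                gt = ground_truth(phantom, t_target, grid)
                gt_name = f"gt_{preset_name}_{int(hr)}bpm_rr{int(ph * 100)}.nii.gz"
                write_nifti(outdir / gt_name, gt)
                cases.append({
                    "preset": preset_name, "heart_rate": hr, "phase": ph,
                    "scan": scan_name, "ground_truth": gt_name,
                    "cycle_index": 1,
                    "window_views": [window.start_index, window.stop_index],
                    "n_scan_views": timeline.n_views,
                    "sinogram_checksum": _checksum(sino.values),
                    "ground_truth_checksum": _checksum(gt.values),
                })
    manifest = {"format_version": "1", "seed": int(seed),
                "grid_n": grid_n, "fov_mm": 250.0,
                "views_per_rotation": views_per_rotation,
                "n_channels": n_channels, "cases": cases}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
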