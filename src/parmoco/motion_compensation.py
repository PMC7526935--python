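"""Linear-in-time motion scaling and motion-compensated backprojection.

The estimated field d(x) maps points at the first PAR time to the
second.  Assuming linear motion over the half rotation separating them,
the displacement of a view acquired at time t relative to the target
(midpoint) time is ``alpha(t) * d(x)`` with

    alpha(t) = (t - target_time) / (t_end - t_start),

so alpha = -1/2 at the first PAR center, 0 at the target and +1/2 at
the second PAR center.  During backprojection every target-frame pixel
is shifted by the view's scaled displacement before its radial position
is read from the filtered row — the "moving voxel" formulation, which
avoids resampling the sinogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import ReconGrid, ReconImage
from .motion_estimation import (BandPassSpec, MotionVectorField,
                                RegistrationConfig, estimate_motion)
from .phantom import ECGModel
from .projector import FanSinogram
from .rebin_fbp import (backproject, ramp_filter, rebin, reconstruct_par,
                        redundancy_weights, select_gating_window)

#: Fractional slack beyond [t_start, t_end] that views in the gating
#: window may occupy (the PAR centers are inset from the window ends by
#: half a fan angle, so edge views extrapolate the linear model slightly).
_TIME_SLACK = 0.25


@dataclass(frozen=True)
class CompensationConfig:
    """Target time for compensation; None means the PAR midpoint."""

    target_time: float | None = None


def temporal_scale(mvf: MotionVectorField, t: float,
                   target_time: float | None = None) -> float:
    """Linear scaling factor alpha(t) of the motion field at time ``t``."""
    dt = mvf.t_end - mvf.t_start
    if dt <= 0:
        raise ValueError("motion field must have t_end > t_start")
    if target_time is None:
        target_time = 0.5 * (mvf.t_start + mvf.t_end)
    slack = _TIME_SLACK * dt
    if not (mvf.t_start - slack <= t <= mvf.t_end + slack):
        raise ValueError(
            f"time {t:.4f}s outside the gating window of the motion field "
            f"[{mvf.t_start:.4f}, {mvf.t_end:.4f}] (+/- slack)")
    return (t - target_time) / dt


def scaled_displacement(mvf: MotionVectorField, t: float, grid: ReconGrid,
                        target_time: float | None = None) -> np.ndarray:
    """Dense displacement field (n, n, 2) scaled to time ``t``."""
    return temporal_scale(mvf, t, target_time) * mvf.displacement_on_grid(grid)


def mc_backproject(filtered, weights: np.ndarray, mvf: MotionVectorField,
                   grid: ReconGrid, cfg: CompensationConfig | None = None
                   ) -> ReconImage:
    """Motion-compensated weighted backprojection.

    With an all-zero field the result is bit-identical to
    :func:`parmoco.rebin_fbp.backproject`.
    """
    if cfg is None:
        cfg = CompensationConfig()
    target = cfg.target_time
    if target is None:
        target = 0.5 * (mvf.t_start + mvf.t_end)
    dense = mvf.displacement_on_grid(grid)
    alphas = np.array([temporal_scale(mvf, t, target)
                       for t in filtered.row_times])
    img = backproject(filtered, weights, grid, displacement=dense,
                      alphas=alphas)
    img.target_time = target
    img.meta["method"] = "sculli"
    return img


def sculli_reconstruct(fan_sino: FanSinogram, ecg: ECGModel,
                       target_phase: float, grid: ReconGrid,
                       cycle_index: int | None = None,
                       band: BandPassSpec | None = None,
                       reg: RegistrationConfig | None = None,
                       comp: CompensationConfig | None = None,
                       apodize: bool = False,
                       return_diagnostics: bool = False
                       ) -> ReconImage | tuple[ReconImage, dict[str, Any]]:
    """Full motion-corrected reconstruction at one cardiac phase.

    Stages: gating-window selection -> fan-to-parallel rebinning ->
    ramp filtering + redundancy weights -> two conjugate partial-angle
    images -> band-pass + FFD registration -> linearly scaled
    motion-compensated backprojection.
    """
    diag: dict[str, Any] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"SCULLI stage {name!r} failed: {exc}") from exc

    window = stage("gating", select_gating_window, fan_sino.timeline, ecg,
                   target_phase, fan_sino.geometry, cycle_index=cycle_index)
    psino = stage("rebin", rebin, fan_sino, window)
    filtered = stage("ramp_filter", ramp_filter, psino, apodize=apodize)
    weights = stage("redundancy_weights", redundancy_weights, filtered)
    par_first = stage("par_first", reconstruct_par, filtered, grid, "first")
    par_last = stage("par_last", reconstruct_par, filtered, grid, "last")
    mvf = stage("motion_estimation", estimate_motion, par_first, par_last,
                band, reg)
    img = stage("mc_backprojection", mc_backproject, filtered, weights, mvf,
                grid, comp)
    img.meta["target_phase"] = target_phase
    img.meta["window"] = (window.start_index, window.stop_index)
    if return_diagnostics:
        diag.update({
            "window": window,
            "par_first": par_first,
            "par_last": par_last,
            "mvf": mvf,
            "registration": mvf.meta,
        })
        return img, diag
    return img
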