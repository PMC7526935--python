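"""Gating-window selection, fan-to-parallel rebinning and weighted FBP.

The reconstruction chain for one cardiac phase:

1. select a contiguous gating window of tube angle ``pi + 2*fan``
   centered on the view acquired closest to the target phase;
2. rebin the fan views to a parallel sinogram (theta = beta + gamma,
   s = R_iso * sin(gamma)); the fully-covered parallel span is then
   ``pi + fan``;
3. ramp-filter rows (band-limited Ram-Lak), apply smooth short-scan
   redundancy weights (conjugate weights sum to one), backproject.

Partial-angle reconstructions (PARs) backproject only the first or last
``fan``-sized wedge of parallel rows with uniform weight: they are
time-resolved edge images for motion estimation, not quantitative
reconstructions.  The two wedges are conjugate — centers a half turn
apart, acquired ``rotation_time / 2`` apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ReconGrid, ReconImage
from .phantom import ECGModel
from .projector import FanSinogram, ScanTimeline, SystemGeometry


# --------------------------------------------------------------------------
# Gating
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingWindow:
    """Contiguous view range used for one reconstruction."""

    target_phase: float
    target_time: float
    width: float           # radians of tube rotation, < 2*pi
    start_index: int
    stop_index: int        # exclusive
    center_index: int

    @property
    def n_views(self) -> int:
        return self.stop_index - self.start_index


def select_gating_window(timeline: ScanTimeline, ecg: ECGModel,
                         target_phase: float, geometry: SystemGeometry,
                         cycle_index: int | None = None,
                         width: float | None = None) -> GatingWindow:
    """Pick the view window of width ``pi + 2*fan`` centered at the phase.

    ``cycle_index`` selects the beat; when None the first beat whose
    window fits inside the acquired timeline is used.
    """
    if width is None:
        width = np.pi + 2.0 * geometry.fan_rad
    if not width < 2.0 * np.pi:
        raise ValueError("gating window must stay below a full rotation")
    n_win = int(round(width / geometry.dbeta))

    def build(ci: int) -> GatingWindow | None:
        t_target = ecg.time_at_phase(target_phase, ci)
        c = int(np.argmin(np.abs(timeline.view_times - t_target)))
        i0 = c - n_win // 2
        i1 = i0 + n_win
        if i0 < 0 or i1 > timeline.n_views:
            return None
        return GatingWindow(target_phase=float(target_phase),
                            target_time=float(t_target), width=float(width),
                            start_index=i0, stop_index=i1, center_index=c)

    if cycle_index is not None:
        win = build(cycle_index)
        if win is None:
            raise ValueError(
                f"gating window (width {np.rad2deg(width):.1f} deg) exceeds "
                f"the acquired data for cycle {cycle_index}")
        return win
    total = timeline.view_times[-1] - timeline.view_times[0]
    for ci in range(int(total / ecg.period) + 2):
        win = build(ci)
        if win is not None:
            return win
    raise ValueError("no cardiac cycle admits a full gating window in this scan")


# --------------------------------------------------------------------------
# Rebinning
# --------------------------------------------------------------------------

@dataclass
class ParallelSinogram:
    """Rebinned parallel projections with one acquisition time per row."""

    values: np.ndarray            # [n_par_angles x n_radial]
    par_angles: np.ndarray        # radians, uniform
    radial_positions: np.ndarray  # mm, uniform
    row_times: np.ndarray         # seconds per parallel angle
    geometry: SystemGeometry
    valid: np.ndarray = field(default=None)  # bool mask, same shape as values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)
        if np.any(np.diff(self.row_times) <= 0):
            raise ValueError("row times must be strictly increasing")

    @property
    def dtheta(self) -> float:
        return float(self.par_angles[1] - self.par_angles[0])

    @property
    def ds(self) -> float:
        return float(self.radial_positions[1] - self.radial_positions[0])

    @property
    def span(self) -> float:
        """Angular span covered, (n-1) * dtheta."""
        return float(self.par_angles[-1] - self.par_angles[0]) + self.dtheta

    def copy_with(self, values: np.ndarray) -> "ParallelSinogram":
        return ParallelSinogram(values=values, par_angles=self.par_angles,
                                radial_positions=self.radial_positions,
                                row_times=self.row_times, geometry=self.geometry,
                                valid=self.valid.copy())


def rebin(fan_sino: FanSinogram, window: GatingWindow,
          n_radial: int | None = None) -> ParallelSinogram:
    """Fan-to-parallel rebinning of the gated views.

    Bilinear interpolation in (beta, gamma); row time taken from the fan
    view whose central ray contributes (beta = theta).  The returned
    parallel angles are restricted to the fully covered range
    ``[beta_first + fan/2, beta_last - fan/2]`` so no corner sample is
    missing; its span is the short-scan span ``pi + fan``.
    """
    geo = fan_sino.geometry
    if n_radial is None:
        n_radial = geo.n_channels
    betas = fan_sino.timeline.view_angles[window.start_index:window.stop_index]
    times = fan_sino.timeline.view_times[window.start_index:window.stop_index]
    vals = fan_sino.values[window.start_index:window.stop_index]
    gamma = geo.gamma
    gmax = gamma[-1]
    dg = gamma[1] - gamma[0]
    db = geo.dbeta

    theta0 = betas[0] + gmax
    theta1 = betas[-1] - gmax
    n_par = int(np.floor((theta1 - theta0) / db + 1e-9)) + 1
    thetas = theta0 + np.arange(n_par) * db

    R = geo.source_to_iso
    s_max = R * np.sin(gmax)
    s = np.linspace(-s_max, s_max, n_radial)
    if np.max(np.abs(s)) > s_max + 1e-9:
        raise ValueError("radial grid exceeds the measurable range")
    gam_s = np.arcsin(np.clip(s / R, -1.0, 1.0))

    i_g = (gam_s - gamma[0]) / dg                       # (n_radial,)
    i_b = (thetas[:, None] - gam_s[None, :] - betas[0]) / db
    coords = np.stack([np.broadcast_to(i_b, (n_par, n_radial)),
                       np.broadcast_to(i_g[None, :], (n_par, n_radial))])
    out = map_coordinates(vals, coords, order=1, mode="nearest")
    valid = (i_b >= -1e-6) & (i_b <= vals.shape[0] - 1 + 1e-6)

    row_times = times[0] + (thetas - betas[0]) / db * geo.dt_view
    return ParallelSinogram(values=out, par_angles=thetas,
                            radial_positions=s, row_times=row_times,
                            geometry=geo, valid=valid)


# --------------------------------------------------------------------------
# Filtering and weights
# --------------------------------------------------------------------------

def _ramlak_kernel(n: int, ds: float) -> np.ndarray:
    """Discrete band-limited ramp (Ram-Lak) kernel, length 2n-1."""
    k = np.arange(-(n - 1), n)
    h = np.zeros_like(k, dtype=float)
    h[k == 0] = 1.0 / (4.0 * ds * ds)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * np.pi * k[odd].astype(float) ** 2 * ds * ds)
    return h


def ramp_filter(psino: ParallelSinogram, apodize: bool = False
                ) -> ParallelSinogram:
    """Row-wise convolution with the Ram-Lak kernel (optionally Hann-
    apodized), scaled by the radial step so FBP recovers mu."""
    n = psino.values.shape[1]
    ds = psino.ds
    h = _ramlak_kernel(n, ds)
    from scipy.fft import next_fast_len, rfft, irfft
    m = next_fast_len(3 * n - 2)
    H = rfft(h, m)
    if apodize:
        freq = np.arange(H.size) / m          # cycles/sample of the padded axis
        H = H * (0.5 + 0.5 * np.cos(2.0 * np.pi * np.clip(freq, 0.0, 0.5)))
    spec = rfft(psino.values, m, axis=1)
    full = irfft(spec * H[None, :], m, axis=1)
    filtered = full[:, n - 1:2 * n - 1] * ds
    return psino.copy_with(filtered)


def redundancy_weights(psino: ParallelSinogram) -> np.ndarray:
    """Smooth short-scan weights on the parallel grid.

    Rays measured twice — rows theta and theta + pi with the radial axis
    flipped — receive cos^2-tapered weights that sum to one; rays
    measured once keep weight one.  Invalid samples get zero weight with
    the conjugate compensating to one.
    """
    span = psino.span
    if span < np.pi - 1e-9:
        raise ValueError("angular span below pi: insufficient data")
    n_par, _ = psino.values.shape
    dth = psino.dtheta
    overlap = span - np.pi
    u = psino.par_angles - psino.par_angles[0]
    w_theta = np.ones(n_par)
    if overlap > 1e-12:
        rise = u < overlap
        w_theta[rise] = np.sin(0.5 * np.pi * u[rise] / overlap) ** 2
        fall = u > np.pi
        w_theta[fall] = np.cos(0.5 * np.pi * (u[fall] - np.pi) / overlap) ** 2
    w = np.broadcast_to(w_theta[:, None], psino.values.shape).copy()
    w[~psino.valid] = 0.0
    # exact pairwise normalization over the doubly measured range
    n_pi = int(round(np.pi / dth))
    for i in range(max(0, n_par - n_pi)):
        j = i + n_pi
        pair = w[i] + w[j][::-1]
        both = pair > 0
        w[i][both] /= pair[both]
        w[j][::-1][both] = 1.0 - w[i][both]
    return w


# --------------------------------------------------------------------------
# Backprojection
# --------------------------------------------------------------------------

def backproject(filtered: ParallelSinogram, weights: np.ndarray,
                grid: ReconGrid, row_slice: slice | None = None,
                displacement: np.ndarray | None = None,
                alphas: np.ndarray | None = None) -> ReconImage:
    """Weighted parallel backprojection onto a square grid.

    With ``displacement`` (an (n, n, 2) mm field) and per-row scale
    factors ``alphas``, each pixel is first moved by
    ``alphas[row] * displacement`` before its radial position is read —
    this is the motion-compensated variant.  ``alphas=None`` (or a zero
    field) reduces bit-exactly to plain backprojection.
    """
    rows = row_slice or slice(None)
    vals = (filtered.values * weights)[rows]
    thetas = filtered.par_angles[rows]
    s = filtered.radial_positions
    X, Y = grid.meshgrid()
    x = X.ravel()
    y = Y.ravel()
    acc = np.zeros(x.size)
    use_motion = displacement is not None and alphas is not None
    if use_motion:
        dx = displacement[..., 0].ravel()
        dy = displacement[..., 1].ravel()
        alphas = np.asarray(alphas, dtype=float)
    for r in range(vals.shape[0]):
        ct, st = np.cos(thetas[r]), np.sin(thetas[r])
        if use_motion and alphas[r] != 0.0:
            sx = (x + alphas[r] * dx) * ct + (y + alphas[r] * dy) * st
        else:
            sx = x * ct + y * st
        acc += np.interp(sx, s, vals[r], left=0.0, right=0.0)
    img = (acc * filtered.dtheta).reshape(grid.n, grid.n)
    return ReconImage(values=img, grid=grid)


@dataclass
class PARImage:
    """Partial-angle reconstruction: a time-resolved wedge image."""

    image: ReconImage
    angular_center: float
    angular_halfwidth: float
    center_time: float


def reconstruct_par(filtered: ParallelSinogram, grid: ReconGrid,
                    which: str, par_angle: float | None = None) -> PARImage:
    """Backproject only the first or last ``par_angle`` wedge of rows.

    Uniform (no redundancy) weighting inside the wedge, global dtheta
    scaling: PAR images serve edge extraction, not quantitation.
    """
    geo = filtered.geometry
    if par_angle is None:
        par_angle = geo.fan_rad
    n_rows = int(round(par_angle / filtered.dtheta))
    n_par = filtered.values.shape[0]
    if n_rows > n_par:
        raise ValueError("requested PAR span exceeds the gating window")
    if which == "first":
        rows = slice(0, n_rows)
    elif which == "last":
        rows = slice(n_par - n_rows, n_par)
    else:
        raise ValueError("which must be 'first' or 'last'")
    w = np.ones_like(filtered.values)
    img = backproject(filtered, w, grid, row_slice=rows)
    thetas = filtered.par_angles[rows]
    times = filtered.row_times[rows]
    return PARImage(image=img,
                    angular_center=float(thetas.mean()),
                    angular_halfwidth=float((thetas[-1] - thetas[0]) / 2.0),
                    center_time=float(times.mean()))


# --------------------------------------------------------------------------
# Full FBP convenience
# --------------------------------------------------------------------------

def fbp_reconstruct(fan_sino: FanSinogram, ecg: ECGModel, target_phase: float,
                    grid: ReconGrid, cycle_index: int | None = None,
                    apodize: bool = False) -> ReconImage:
    """Short-scan weighted FBP at one cardiac phase (the baseline method)."""
    window = select_gating_window(fan_sino.timeline, ecg, target_phase,
                                  fan_sino.geometry, cycle_index=cycle_index)
    psino = rebin(fan_sino, window)
    filtered = ramp_filter(psino, apodize=apodize)
    weights = redundancy_weights(filtered)
    img = backproject(filtered, weights, grid)
    img.target_time = window.target_time
    img.meta["method"] = "fbp"
    img.meta["target_phase"] = target_phase
    return img
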