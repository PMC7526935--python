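"""Time-resolved analytic fan-beam forward projection.

Third-generation geometry with an equiangular (curved) detector.  The
tube angle beta is measured from +y, counter-clockwise; the source sits
at ``R_iso * (-sin(beta), cos(beta))``.  Channel k views the in-fan
angle ``gamma_k = (k - (n-1)/2) * fan/(n-1)`` so that a fan ray maps to
the parallel-beam ray with angle ``theta = beta + gamma`` and radial
position ``s = R_iso * sin(gamma)``.

The phantom *moves between views*: row v of the sinogram is the set of
line integrals through the phantom frozen at ``view_times[v]``.  Line
integrals are exact closed-form ellipse chords; nested (host-declared)
primitives contribute additively via mu-differences, which reproduces
painting-order semantics exactly for fully nested structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DynamicPhantom, FrozenPrimitive


@dataclass(frozen=True)
class SystemGeometry:
    """Fan-beam scanner description (2D axial)."""

    source_to_iso: float = 600.0      # mm
    source_to_detector: float = 1100.0  # mm
    n_channels: int = 736
    fan_angle: float = 52.0           # degrees, full fan
    views_per_rotation: int = 720
    rotation_time: float = 0.25       # seconds per rotation

    def __post_init__(self) -> None:
        if not (self.source_to_detector > self.source_to_iso > 0):
            raise ValueError("require source_to_detector > source_to_iso > 0")
        if not (0.0 < self.fan_angle < 90.0):
            raise ValueError("fan angle must be in (0, 90) degrees")
        if self.n_channels < 2 or self.views_per_rotation < 2:
            raise ValueError("need at least 2 channels and views")
        if self.rotation_time <= 0:
            raise ValueError("rotation time must be positive")

    @property
    def fan_rad(self) -> float:
        return np.deg2rad(self.fan_angle)

    @property
    def gamma(self) -> np.ndarray:
        """Per-channel in-fan angles (radians), edge channels at +-fan/2."""
        k = np.arange(self.n_channels)
        dg = self.fan_rad / (self.n_channels - 1)
        return (k - (self.n_channels - 1) / 2.0) * dg

    @property
    def fov_radius(self) -> float:
        """Radius of the measured field of view: R_iso * sin(fan/2)."""
        return self.source_to_iso * np.sin(self.fan_rad / 2.0)

    @property
    def dbeta(self) -> float:
        return 2.0 * np.pi / self.views_per_rotation

    @property
    def dt_view(self) -> float:
        return self.rotation_time / self.views_per_rotation

    def source_position(self, beta: float | np.ndarray) -> np.ndarray:
        b = np.asarray(beta, dtype=float)
        return np.stack([-self.source_to_iso * np.sin(b),
                         self.source_to_iso * np.cos(b)], axis=-1)


@dataclass(frozen=True)
class ScanTimeline:
    """Uniformly sampled tube angles and acquisition times."""

    view_angles: np.ndarray  # radians, strictly increasing
    view_times: np.ndarray   # seconds, strictly increasing

    def __post_init__(self) -> None:
        a = np.asarray(self.view_angles, dtype=float)
        t = np.asarray(self.view_times, dtype=float)
        if a.shape != t.shape or a.ndim != 1:
            raise ValueError("angles and times must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("view times must be strictly increasing")
        object.__setattr__(self, "view_angles", a)
        object.__setattr__(self, "view_times", t)

    @property
    def n_views(self) -> int:
        return self.view_angles.size

    @staticmethod
    def for_scan(geometry: SystemGeometry, n_rotations: float = 1.0,
                 start_angle: float = 0.0, start_time: float = 0.0) -> "ScanTimeline":
        n = int(round(n_rotations * geometry.views_per_rotation))
        k = np.arange(n)
        return ScanTimeline(view_angles=start_angle + k * geometry.dbeta,
                            view_times=start_time + k * geometry.dt_view)


@dataclass
class FanSinogram:
    """Raw fan-beam line integrals [n_views x n_channels] with timestamps."""

    values: np.ndarray
    geometry: SystemGeometry
    timeline: ScanTimeline

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.timeline.n_views, self.geometry.n_channels)
        if self.values.shape != expected:
            raise ValueError(f"sinogram shape {self.values.shape} != {expected}")


# --------------------------------------------------------------------------
# Rays and analytic chords
# --------------------------------------------------------------------------

def ray_for(geometry: SystemGeometry, view_angle: float, channel: int
            ) -> tuple[np.ndarray, np.ndarray]:
    """Ray (origin point, unit direction) of one detector channel."""
    if not 0 <= channel < geometry.n_channels:
        raise IndexError(f"channel {channel} out of range")
    gamma = geometry.gamma[channel]
    theta = view_angle + gamma
    origin = geometry.source_position(view_angle)
    direction = np.array([np.sin(theta), -np.cos(theta)])
    return origin, direction


def _ellipse_chords(origin: np.ndarray, directions: np.ndarray,
                    center, semi_axes, tilt: float) -> np.ndarray:
    """Chord lengths of rays through one ellipse (vectorized over rays)."""
    c, s = np.cos(tilt), np.sin(tilt)
    ox = origin[0] - center[0]
    oy = origin[1] - center[1]
    oxr = c * ox + s * oy
    oyr = -s * ox + c * oy
    dxr = c * directions[..., 0] + s * directions[..., 1]
    dyr = -s * directions[..., 0] + c * directions[..., 1]
    a, b = semi_axes
    A = (dxr / a) ** 2 + (dyr / b) ** 2
    B = 2.0 * (oxr * dxr / a ** 2 + oyr * dyr / b ** 2)
    C = (oxr / a) ** 2 + (oyr / b) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    return np.sqrt(np.clip(disc, 0.0, None)) / A


def _geometric_chords(fp: FrozenPrimitive, origin, directions) -> np.ndarray:
    ch = _ellipse_chords(origin, directions, fp.center, fp.semi_axes, fp.tilt)
    if fp.shape == "annulus":
        ch = ch - _ellipse_chords(origin, directions, fp.center,
                                  fp.inner_semi_axes, fp.tilt)
    return ch


def primitive_line_integral(fp: FrozenPrimitive, ray) -> float:
    """mu x chord length of one ray through one frozen primitive.

    Overlap between primitives is resolved at the phantom level (nested
    additive deltas); this is the raw single-primitive integral.
    """
    origin, direction = ray
    ch = _geometric_chords(fp, np.asarray(origin, float),
                           np.asarray(direction, float)[None, :])
    return float(fp.mu * ch[0])


def _snapshot_projection(frozen: list[FrozenPrimitive], geometry: SystemGeometry,
                         beta: float) -> np.ndarray:
    """One sinogram row: additive nested projection of a frozen snapshot."""
    origin = geometry.source_position(beta)
    theta = beta + geometry.gamma
    directions = np.stack([np.sin(theta), -np.cos(theta)], axis=-1)
    mu_of = {fp.name: fp.mu for fp in frozen}
    row = np.zeros(geometry.n_channels)
    for fp in frozen:
        dmu = fp.mu - (mu_of[fp.host] if fp.host is not None else 0.0)
        if dmu == 0.0:
            continue
        row += dmu * _geometric_chords(fp, origin, directions)
    return row


def forward_project(phantom: DynamicPhantom, geometry: SystemGeometry,
                    timeline: ScanTimeline) -> FanSinogram:
    """Project the moving phantom: row v freezes it at ``view_times[v]``."""
    half = phantom.fov_extent / 2.0
    # every primitive must stay inside the measured FOV (no truncation)
    for ph in np.linspace(0.0, 1.0, 9, endpoint=False):
        for fp in phantom.snapshot_at_phase(ph):
            if fp.max_radius() > geometry.fov_radius:
                raise ValueError(
                    f"primitive {fp.name} leaves the scan FOV "
                    f"(radius {geometry.fov_radius:.1f} mm); truncation "
                    "is not supported")
    del half
    values = np.empty((timeline.n_views, geometry.n_channels))
    for v in range(timeline.n_views):
        frozen = phantom.snapshot(timeline.view_times[v])
        values[v] = _snapshot_projection(frozen, geometry,
                                         timeline.view_angles[v])
    return FanSinogram(values=values, geometry=geometry, timeline=timeline)


def project_snapshot(frozen: list[FrozenPrimitive], geometry: SystemGeometry,
                     timeline: ScanTimeline) -> FanSinogram:
    """Project a *static* snapshot over a timeline (no motion)."""
    values = np.stack([
        _snapshot_projection(frozen, geometry, beta)
        for beta in timeline.view_angles
    ])
    return FanSinogram(values=values, geometry=geometry, timeline=timeline)


# --------------------------------------------------------------------------
# Noise
# --------------------------------------------------------------------------

#: Transmitted-count floor applied before the log, in photons.
NOISE_COUNT_FLOOR = 0.5


def add_noise(sino: FanSinogram, photons_per_ray: float, seed: int
              ) -> FanSinogram:
    """Poisson photon noise in the transmission domain.

    Each line integral p is replaced by ``-log(N / photons)`` with
    ``N ~ Poisson(photons * exp(-p))`` clipped below at
    ``NOISE_COUNT_FLOOR`` counts.  Off by default everywhere else in the
    package: the reference simulation study is noiseless.
    """
    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be positive")
    rng = np.random.default_rng(seed)
    transmitted = photons_per_ray * np.exp(-sino.values)
    counts = rng.poisson(transmitted).astype(float)
    counts = np.clip(counts, NOISE_COUNT_FLOOR, None)
    noisy = -np.log(counts / photons_per_ray)
    return FanSinogram(values=noisy, geometry=sino.geometry,
                       timeline=sino.timeline)
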