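"""ECG-driven dynamic analytic phantom.

The phantom is an ordered list of analytic primitives (ellipses, disks,
annuli) whose geometric parameters are continuous periodic functions of
the cardiac phase.  Painting order resolves overlap: at any point the
attenuation is that of the last primitive covering it.  Presets emulate
three experimental setups:

``xcat_like``
    A contracting myocardial-wall annulus around two chamber ellipses of
    different contrast, with three small high-contrast "artery" disks
    embedded in the wall — a desk-scale analog of an anthropomorphic
    beating-heart simulation.
``mocomo_like``
    Six rods of 3/4/5 mm diameter (half with a stenosis notch) on a
    carousel performing a rigid oscillating rotation plus translation —
    a coronary-motion phantom analog.
``alpha_like``
    A pulsating contrast-filled balloon with two rods attached to its
    surface — a chamber/myocardial-wall motion analog.
``static``
    Any preset with all motion amplitudes forced to zero.

Nesting discipline: a primitive may declare the *host* primitive it is
fully contained in (e.g. arteries inside the wall annulus).  Arbitrary
partial overlaps are rejected at construction; this keeps analytic line
integrals exact (painting reduces to additive mu-differences against the
host).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import ReconGrid, ReconImage, hu_to_mu


# --------------------------------------------------------------------------
# ECG
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ECGModel:
    """Idealized periodic ECG: a heart rate and the time of the first R peak."""

    heart_rate: float  # beats per minute
    t0_rpeak: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive (bpm)")

    @property
    def period(self) -> float:
        """R-R interval in seconds."""
        return 60.0 / self.heart_rate

    def phase(self, t: float | np.ndarray) -> float | np.ndarray:
        """Cardiac phase in [0, 1): fraction of the R-R interval elapsed."""
        return cardiac_phase(self, t)

    def time_at_phase(self, phase: float, cycle_index: int = 0) -> float:
        """Absolute time of ``phase`` within beat ``cycle_index``."""
        return self.t0_rpeak + (cycle_index + phase) * self.period


def cardiac_phase(ecg: ECGModel, t: float | np.ndarray) -> float | np.ndarray:
    """R-R phase of time ``t``: ``((t - t0) mod period) / period`` in [0, 1)."""
    if ecg.heart_rate <= 0:
        raise ValueError("heart rate must be positive (bpm)")
    ph = np.mod(np.asarray(t, dtype=float) - ecg.t0_rpeak, ecg.period) / ecg.period
    ph = np.where(ph >= 1.0, ph - 1.0, ph)  # guard the mod(x, p) == p float edge
    if np.ndim(t) == 0:
        return float(ph)
    return ph


# --------------------------------------------------------------------------
# Motion laws
# --------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def two_plateau_modulation(phase, rest_center, rest_halfwidth,
                           peak_center, peak_halfwidth):
    """Periodic modulation in [0, 1]: 0 on a plateau around ``rest_center``,
    1 on a plateau around ``peak_center``, smoothstep transitions between.

    All arguments are cycle fractions; the function is C1-continuous and
    has period 1.
    """
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    # unwrap relative to the end of the rest plateau
    a0 = rest_center + rest_halfwidth        # rise starts
    a1 = np.mod(peak_center - peak_halfwidth - a0, 1.0)   # rise ends
    b0 = np.mod(peak_center + peak_halfwidth - a0, 1.0)   # fall starts
    b1 = np.mod(rest_center - rest_halfwidth - a0, 1.0)   # fall ends
    u = np.mod(phi - a0, 1.0)
    m = np.zeros_like(u)
    rise = u < a1
    m[rise] = _smoothstep(u[rise] / max(a1, 1e-12))
    plateau = (u >= a1) & (u < b0)
    m[plateau] = 1.0
    fall = (u >= b0) & (u < b1)
    m[fall] = 1.0 - _smoothstep((u[fall] - b0) / max(b1 - b0, 1e-12))
    # u >= b1: rest plateau, already 0
    if np.ndim(phase) == 0:
        return float(m)
    return m


@dataclass(frozen=True)
class MotionLaw:
    """Periodic scalar/vector motion law driven by cardiac phase.

    kind
        ``harmonic``: cosine modulation, at rest (zero derivative, zero
        displacement) at ``phase_of_rest``.
        ``rest_and_jerk``: two-plateau smoothstep between a rest
        configuration (modulation 0, plateau of width ``duty`` around
        ``phase_of_rest``) and a peak configuration (modulation 1,
        plateau of width ``peak_duty`` around ``phase_of_peak``).
        ``rigid_orbit``: uniform circular motion of radius
        ``amplitude / 2`` about the mean position.
    amplitude
        Peak-to-peak displacement bound in mm (or a dimensionless scale
        when used to modulate shape parameters).
    """

    kind: str = "harmonic"
    amplitude: float = 0.0
    phase_of_rest: float = 0.75
    duty: float = 0.2
    phase_of_peak: float | None = None
    peak_duty: float | None = None
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "rest_and_jerk", "rigid_orbit"):
            raise ValueError(f"unknown motion law kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def _peak(self) -> float:
        return (self.phase_of_rest + 0.5) % 1.0 if self.phase_of_peak is None \
            else self.phase_of_peak

    def modulation(self, phase):
        """Scalar modulation in [0, 1]; 0 at rest, 1 at peak."""
        if self.kind == "harmonic":
            return 0.5 - 0.5 * np.cos(2.0 * np.pi * (np.asarray(phase, float)
                                                     - self.phase_of_rest))
        if self.kind == "rest_and_jerk":
            pk = self.peak_duty if self.peak_duty is not None else self.duty
            return two_plateau_modulation(phase, self.phase_of_rest,
                                          self.duty / 2.0, self._peak, pk / 2.0)
        # rigid_orbit has no scalar rest/peak notion; expose orbit angle fraction
        return np.mod(np.asarray(phase, float) - self.phase_of_rest, 1.0)

    def displacement(self, phase) -> np.ndarray:
        """Displacement vector (mm) at ``phase``; |d| <= amplitude, 0 at rest."""
        if self.kind == "rigid_orbit":
            th = 2.0 * np.pi * (np.asarray(phase, float) - self.phase_of_rest)
            r = self.amplitude / 2.0
            return np.stack([r * (np.cos(th) - 1.0), r * np.sin(th)], axis=-1)
        m = np.asarray(self.modulation(phase), dtype=float)
        d = np.asarray(self.direction, dtype=float)
        d = d / (np.linalg.norm(d) or 1.0)
        return m[..., None] * self.amplitude * d


# --------------------------------------------------------------------------
# Primitives
# --------------------------------------------------------------------------

_SHAPES = ("ellipse", "disk", "annulus")


@dataclass(frozen=True)
class FrozenPrimitive:
    """A primitive with all parameters evaluated at one phase."""

    name: str
    shape: str
    mu: float
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    tilt: float = 0.0
    inner_semi_axes: tuple[float, float] | None = None
    host: str | None = None

    def _frame(self, x, y):
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        c, s = np.cos(self.tilt), np.sin(self.tilt)
        return c * dx + s * dy, -s * dx + c * dy

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask: points covered by this primitive."""
        u, v = self._frame(x, y)
        a, b = self.semi_axes
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if self.shape == "annulus":
            ai, bi = self.inner_semi_axes
            inside &= (u / ai) ** 2 + (v / bi) ** 2 > 1.0
        return inside

    def sample_points(self, n: int = 64) -> np.ndarray:
        """Points spread through the covered region (for containment checks)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        if self.shape == "annulus":
            ai, bi = self.inner_semi_axes
            fracs = np.linspace(0.02, 0.98, 5)
            us = np.concatenate([(ai + f * (a - ai)) * np.cos(t) for f in fracs])
            vs = np.concatenate([(bi + f * (b - bi)) * np.sin(t) for f in fracs])
        else:
            fracs = np.array([0.02, 0.3, 0.6, 0.85, 0.99])
            us = np.concatenate([f * a * np.cos(t) for f in fracs])
            vs = np.concatenate([f * b * np.sin(t) for f in fracs])
        c, s = np.cos(self.tilt), np.sin(self.tilt)
        x = self.center[0] + c * us - s * vs
        y = self.center[1] + s * us + c * vs
        return np.stack([x, y], axis=-1)

    def max_radius(self) -> float:
        """Distance from the origin to the farthest covered point."""
        return float(np.hypot(*self.center) + max(self.semi_axes))


ParamFn = Callable[[float], float]
Param2Fn = Callable[[float], tuple[float, float]]


def _const(v):
    def f(_phase):
        return v
    return f


@dataclass(frozen=True)
class TimeVaryingPrimitive:
    """Analytic primitive whose parameters are functions of cardiac phase."""

    name: str
    shape: str
    mu: float
    center: Param2Fn
    semi_axes: Param2Fn
    tilt: ParamFn = field(default_factory=lambda: _const(0.0))
    inner_semi_axes: Param2Fn | None = None
    host: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; use one of {_SHAPES}")
        if self.mu < 0:
            raise ValueError("attenuation must be non-negative")
        if self.shape == "annulus" and self.inner_semi_axes is None:
            raise ValueError("annulus needs inner_semi_axes")

    def freeze(self, phase: float) -> FrozenPrimitive:
        sa = tuple(float(v) for v in self.semi_axes(phase))
        if min(sa) <= 0:
            raise ValueError(f"{self.name}: semi-axes must stay positive")
        inner = None
        if self.inner_semi_axes is not None:
            inner = tuple(float(v) for v in self.inner_semi_axes(phase))
        return FrozenPrimitive(
            name=self.name, shape=self.shape, mu=self.mu,
            center=tuple(float(v) for v in self.center(phase)),
            semi_axes=sa, tilt=float(self.tilt(phase)),
            inner_semi_axes=inner, host=self.host,
        )


def static_primitive(name, shape, mu, center, semi_axes, tilt=0.0,
                     inner_semi_axes=None, host=None) -> TimeVaryingPrimitive:
    """Primitive with phase-independent parameters."""
    return TimeVaryingPrimitive(
        name=name, shape=shape, mu=mu, center=_const(tuple(center)),
        semi_axes=_const(tuple(semi_axes)), tilt=_const(tilt),
        inner_semi_axes=None if inner_semi_axes is None else _const(tuple(inner_semi_axes)),
        host=host,
    )


# --------------------------------------------------------------------------
# Phantom
# --------------------------------------------------------------------------

class PhantomConstructionError(ValueError):
    """Raised when a phantom violates the nesting/extent discipline."""


_VALIDATION_PHASES = np.linspace(0.0, 1.0, 17, endpoint=False)


@dataclass
class DynamicPhantom:
    """Ordered primitives + ECG; later primitives overwrite earlier ones."""

    primitives: list[TimeVaryingPrimitive]
    ecg: ECGModel
    fov_extent: float = 250.0  # mm, edge length of the square FOV

    def __post_init__(self) -> None:
        self._validate()

    # -- construction checks ------------------------------------------------
    def _validate(self) -> None:
        names = [p.name for p in self.primitives]
        if len(set(names)) != len(names):
            raise PhantomConstructionError("primitive names must be unique")
        for k, p in enumerate(self.primitives):
            if p.host is not None and p.host not in names[:k]:
                raise PhantomConstructionError(
                    f"{p.name}: host {p.host!r} must be an earlier primitive")
        half = self.fov_extent / 2.0
        for ph in _VALIDATION_PHASES:
            frozen = [p.freeze(ph) for p in self.primitives]
            for fp in frozen:
                if fp.max_radius() > half * np.sqrt(2.0):
                    raise PhantomConstructionError(
                        f"{fp.name} leaves the FOV at phase {ph:.3f}")
            self._check_overlaps(frozen, ph)

    @staticmethod
    def _check_overlaps(frozen: list[FrozenPrimitive], phase: float) -> None:
        for j, pj in enumerate(frozen):
            pts = pj.sample_points()
            for i in range(j):
                pi = frozen[i]
                ins = pi.contains(pts[:, 0], pts[:, 1])
                frac = float(np.mean(ins))
                if pj.host == pi.name and frac < 1.0:
                    raise PhantomConstructionError(
                        f"{pj.name} is not fully inside its host {pi.name} "
                        f"at phase {phase:.3f}")
                if pj.host != pi.name and 0.0 < frac < 1.0:
                    raise PhantomConstructionError(
                        f"{pj.name} partially overlaps {pi.name} at phase "
                        f"{phase:.3f}; declare nesting via host= or separate them")

    # -- evaluation ---------------------------------------------------------
    def snapshot(self, t: float) -> list[FrozenPrimitive]:
        """All primitives frozen at the cardiac phase of time ``t``."""
        if not np.isfinite(t):
            raise ValueError("time must be finite")
        ph = cardiac_phase(self.ecg, t)
        return [p.freeze(ph) for p in self.primitives]

    def snapshot_at_phase(self, phase: float) -> list[FrozenPrimitive]:
        return [p.freeze(phase % 1.0) for p in self.primitives]


def rasterize(frozen: Sequence[FrozenPrimitive], grid: ReconGrid,
              supersample: int = 1) -> ReconImage:
    """Paint frozen primitives onto a pixel grid (last covering wins).

    ``supersample`` > 1 averages a k x k subpixel sampling per pixel,
    reducing partial-volume bias in ground-truth images used for metrics.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    k = int(supersample)
    n = grid.n * k
    c = (np.arange(n) + 0.5 - n / 2.0) * (grid.pixel_size / k)
    X, Y = np.meshgrid(c, c)
    img = np.zeros((n, n), dtype=float)
    for fp in frozen:
        mask = fp.contains(X, Y)
        img[mask] = fp.mu
    if k > 1:
        img = img.reshape(grid.n, k, grid.n, k).mean(axis=(1, 3))
    return ReconImage(values=img, grid=grid)


def ground_truth(phantom: DynamicPhantom, t: float, grid: ReconGrid,
                 supersample: int = 4) -> ReconImage:
    """Supersampled rasterization of the phantom frozen at time ``t``."""
    img = rasterize(phantom.snapshot(t), grid, supersample=supersample)
    img.target_time = t
    return img


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

def _lerp2(p0, p1, law: MotionLaw) -> Param2Fn:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)

    def f(phase):
        m = law.modulation(phase)
        return tuple((1.0 - m) * p0 + m * p1)
    return f


def _xcat_like(heart_rate=80.0, t0_rpeak=0.0, fov_extent=250.0,
               amplitude_scale=1.0, artery_diameter=3.0,
               hu_wall=180.0, hu_lv=350.0, hu_rv=150.0, hu_artery=450.0,
               hu_body=0.0, rest_phase=0.90, peak_phase=0.40,
               rest_duty=0.08, peak_duty=0.08) -> DynamicPhantom:
    """Contracting myocardial annulus, two chambers of distinct contrast,
    three embedded artery disks.  A short end-systolic rest around
    ``peak_phase`` (contracted) and a diastasis rest around
    ``rest_phase`` (relaxed), with long smooth contraction/relaxation
    ramps between them, so the common R-R 30%/70% reconstruction targets
    sit mid-motion the way they do for a real heart."""
    a = float(np.clip(amplitude_scale, 0.0, 2.0))
    law = MotionLaw(kind="rest_and_jerk", amplitude=1.0, phase_of_rest=rest_phase,
                    duty=rest_duty, phase_of_peak=peak_phase, peak_duty=peak_duty)

    heart_c = np.array([12.0, -4.0])
    # diastole (modulation 0) -> systole (modulation 1), blended by amplitude_scale
    out_d, out_s = np.array([48.0, 42.0]), np.array([40.0, 35.0])
    inn_d, inn_s = np.array([34.0, 29.0]), np.array([24.0, 21.0])
    out_s = out_d + a * (out_s - out_d)
    inn_s = inn_d + a * (inn_s - inn_d)

    wall = TimeVaryingPrimitive(
        name="wall", shape="annulus", mu=hu_to_mu(hu_wall),
        center=_const(tuple(heart_c)),
        semi_axes=_lerp2(out_d, out_s, law),
        inner_semi_axes=_lerp2(inn_d, inn_s, law),
        host="body",
    )

    def chamber(name, hu, frac_c, sa_d, sa_s):
        sa_s = np.asarray(sa_d) + a * (np.asarray(sa_s) - np.asarray(sa_d))

        def center(phase):
            m = law.modulation(phase)
            inn = (1.0 - m) * inn_d + m * inn_s
            return tuple(heart_c + np.asarray(frac_c) * inn)
        return TimeVaryingPrimitive(
            name=name, shape="ellipse", mu=hu_to_mu(hu), center=center,
            semi_axes=_lerp2(sa_d, sa_s, law), host="body",
        )

    lv = chamber("lv", hu_lv, (-0.45, 0.05), (15.0, 13.0), (10.0, 8.5))
    rv = chamber("rv", hu_rv, (0.48, -0.05), (12.0, 10.0), (8.0, 6.5))

    r_art = artery_diameter / 2.0
    arteries = []
    for label, psi in (("rca", np.deg2rad(-35.0)), ("lad", np.deg2rad(95.0)),
                       ("lcx", np.deg2rad(205.0))):
        def center(phase, psi=psi):
            m = law.modulation(phase)
            mid = 0.5 * ((1.0 - m) * (out_d + inn_d) + m * (out_s + inn_s))
            return (heart_c[0] + mid[0] * np.cos(psi),
                    heart_c[1] + mid[1] * np.sin(psi))
        arteries.append(TimeVaryingPrimitive(
            name=label, shape="disk", mu=hu_to_mu(hu_artery), center=center,
            semi_axes=_const((r_art, r_art)), host="wall",
        ))

    body = static_primitive("body", "ellipse", hu_to_mu(hu_body),
                            center=(0.0, 0.0), semi_axes=(105.0, 88.0))
    ecg = ECGModel(heart_rate=heart_rate, t0_rpeak=t0_rpeak)
    return DynamicPhantom(primitives=[body, wall, lv, rv] + arteries,
                          ecg=ecg, fov_extent=fov_extent)


def _mocomo_like(heart_rate=80.0, t0_rpeak=0.0, fov_extent=250.0,
                 amplitude_scale=1.0, amplitude=8.0, hu_rod=400.0,
                 hu_bath=0.0, carousel_radius=32.0) -> DynamicPhantom:
    """Six rods (diameters 3/4/5 mm, one of each with a stenosis notch)
    on a rigidly oscillating carousel inside a water bath."""
    amp = amplitude * float(np.clip(amplitude_scale, 0.0, 2.0))
    # oscillation angle giving a peak-to-peak rod excursion ~ amp
    theta_amp = amp / (2.0 * carousel_radius)
    trans_amp = 0.25 * amp

    def assembly(phase):
        th = theta_amp * np.sin(2.0 * np.pi * phase)
        shift = np.array([0.0, trans_amp * np.sin(2.0 * np.pi * phase + 0.7)])
        return th, shift

    bath = static_primitive("bath", "disk", hu_to_mu(hu_bath),
                            center=(0.0, 0.0), semi_axes=(85.0, 85.0))
    prims = [bath]
    diameters = [3.0, 4.0, 5.0, 3.0, 4.0, 5.0]
    for k, d in enumerate(diameters):
        psi0 = 2.0 * np.pi * k / 6.0
        r = d / 2.0
        notched = k >= 3

        def rod_center(phase, psi0=psi0):
            th, shift = assembly(phase)
            return (carousel_radius * np.cos(psi0 + th) + shift[0],
                    carousel_radius * np.sin(psi0 + th) + shift[1])

        prims.append(TimeVaryingPrimitive(
            name=f"rod{k}", shape="disk", mu=hu_to_mu(hu_rod),
            center=rod_center, semi_axes=_const((r, r)), host="bath"))
        if notched:
            # lumen-narrowing notch: low-attenuation disk inside the rod
            off, rn = 0.40 * r, 0.45 * r

            def notch_center(phase, psi0=psi0, off=off):
                th, shift = assembly(phase)
                psi = psi0 + th
                cx = carousel_radius * np.cos(psi) + shift[0]
                cy = carousel_radius * np.sin(psi) + shift[1]
                return (cx + off * np.cos(psi), cy + off * np.sin(psi))

            prims.append(TimeVaryingPrimitive(
                name=f"rod{k}_notch", shape="disk", mu=hu_to_mu(hu_bath),
                center=notch_center, semi_axes=_const((rn, rn)),
                host=f"rod{k}"))
    ecg = ECGModel(heart_rate=heart_rate, t0_rpeak=t0_rpeak)
    return DynamicPhantom(primitives=prims, ecg=ecg, fov_extent=fov_extent)


def _alpha_like(heart_rate=80.0, t0_rpeak=0.0, fov_extent=250.0,
                amplitude_scale=1.0, hu_balloon=275.0, hu_rod=400.0,
                hu_bath=0.0, rest_phase=0.75) -> DynamicPhantom:
    """Pulsating contrast-filled balloon (250-300 HU range by default)
    with two artery rods riding on its surface."""
    a = float(np.clip(amplitude_scale, 0.0, 2.0))
    law = MotionLaw(kind="harmonic", amplitude=1.0, phase_of_rest=rest_phase)
    r0, dr = 30.0, 5.0 * a
    rod_r = 2.0
    c = np.array([-5.0, 3.0])

    def balloon_sa(phase):
        r = r0 - dr * law.modulation(phase)
        return (r, r)

    bath = static_primitive("bath", "disk", hu_to_mu(hu_bath),
                            center=(0.0, 0.0), semi_axes=(85.0, 85.0))
    balloon = TimeVaryingPrimitive(
        name="balloon", shape="disk", mu=hu_to_mu(hu_balloon),
        center=_const(tuple(c)), semi_axes=balloon_sa, host="bath")
    rods = []
    for label, psi in (("rod_a", np.deg2rad(55.0)), ("rod_b", np.deg2rad(210.0))):
        def center(phase, psi=psi):
            r = r0 - dr * law.modulation(phase)
            rr = r + rod_r + 0.3  # riding just off the surface
            return (c[0] + rr * np.cos(psi), c[1] + rr * np.sin(psi))
        rods.append(TimeVaryingPrimitive(
            name=label, shape="disk", mu=hu_to_mu(hu_rod), center=center,
            semi_axes=_const((rod_r, rod_r)), host="bath"))
    ecg = ECGModel(heart_rate=heart_rate, t0_rpeak=t0_rpeak)
    return DynamicPhantom(primitives=[bath, balloon] + rods,
                          ecg=ecg, fov_extent=fov_extent)


_PRESETS = {
    "xcat_like": _xcat_like,
    "mocomo_like": _mocomo_like,
    "alpha_like": _alpha_like,
}


def preset(name: str, **options) -> DynamicPhantom:
    """Build a named phantom preset.

    ``static`` is any preset (default ``xcat_like``) with zero motion:
    ``preset("static", base="mocomo_like", ...)``.
    """
    if name == "static":
        base = options.pop("base", "xcat_like")
        options["amplitude_scale"] = 0.0
        return preset(base, **options)
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from "
            f"{sorted(_PRESETS) + ['static']}") from None
    return builder(**options)
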