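# Methods

This note documents the models, parameter choices and numerical
decisions behind `parmoco`, and what the test suite does and does not
demonstrate.

## Forward model

The scanner is a third-generation 2D fan-beam system with an
equiangular (curved) detector.  Defaults: source-to-isocenter 600 mm,
source-to-detector 1100 mm, full fan angle 52 deg, 736 channels, 720
views/rotation, 0.25 s/rotation.  The 52 deg fan and 0.25 s rotation
are the parameters of the method being reproduced; the distances and
sampling are plausible desk-scale choices (the measured field of view,
`2 R sin(fan/2) ~ 526 mm`, comfortably covers the 250 mm reconstruction
FOV) and are configurable.  Coordinates: x to the patient right, y up,
tube angle measured from +y; pixel centers at `(i + 0.5 - n/2) * px`.

Projections are exact ellipse/annulus chord integrals.  The object
moves *between* views: sinogram row v freezes the phantom at that
view's acquisition time, which is what makes motion artifacts (and
their correction) physically meaningful in this simulator.  Overlapping
primitives follow painting order (last covering wins).  To keep line
integrals closed-form, presets declare nesting explicitly: a primitive
fully contained in a host contributes `(mu - mu_host) * chord`
additively.  Containment is verified numerically over a cycle at
construction; undeclared partial overlaps are rejected rather than
approximated.  Noise is off by default (the reference evaluation is
noiseless); a seeded Poisson transmission model is available, with
transmitted counts floored at 0.5 photons before the log.

## Dynamic phantom

The cardiac-phase model is an idealized periodic ECG
(`phase(t) = ((t - t0) mod T)/T`, `T = 60/bpm`).  Motion laws map phase
to displacement: `harmonic` (cosine), `rigid_orbit` (uniform circular),
and `rest_and_jerk` — a C1 two-plateau smoothstep with a rest
configuration and a peak configuration.

`xcat_like` is the quantitative workhorse: a body ellipse (water), a
contracting myocardial annulus (outer 48x42 -> 40x35 mm, inner 34x29 ->
24x21 mm), two chambers of deliberately different contrast (LV-analog
350 HU, RV-analog 150 HU), and three 3 mm artery disks (450 HU) riding
the mid-wall at RCA/LAD/LCX-like positions.  The wall is 180 HU so the
line-profile experiment operates in the 150–200 HU regime.  Contrast
levels and motion amplitudes of the original anthropomorphic simulation
are not published; these values were fixed once as clinically plausible
and are configuration, not claims of fidelity.  The artery excursion
over a full cycle is ~9 mm, which keeps the worst inter-PAR (125 ms)
displacement below the 14.3 mm model cap at all simulated heart rates.

Kinematics: end-systolic rest around R-R 40% and diastasis around
R-R 90% (0.08-cycle plateaus, long smoothstep ramps between).  The
common 30%/70% reconstruction targets therefore sit mid-motion, as they
do for a real heart at 60–100 bpm — this is what gives the baseline FBP
its motion artifacts and the correction something to correct.  Placing
a rest plateau at an evaluation phase makes FBP nearly perfect there
and the comparison uninformative.

`mocomo_like` (six rods of 3/4/5 mm, half with a low-attenuation
stenosis notch, on a carousel with oscillating rotation plus
translation) and `alpha_like` (pulsating 275 HU balloon with two
surface rods) mirror the two physical-phantom geometries; `static`
zeroes any preset's motion.

Ground-truth images are rasterized at pixel centers with optional k x k
supersampling (default 4x for metric references, reducing
partial-volume bias).

## Reconstruction

Fan-to-parallel rebinning uses bilinear interpolation in (beta, gamma);
the parallel grid is restricted to the fully covered span `pi + fan`,
so no corner extrapolation occurs.  Each parallel row carries the
acquisition time of the fan view supplying its central ray; the +-26
deg spread of source angles feeding one row (~18 ms) is the accepted
approximation behind "one time per view".

Filtering is the discrete band-limited Ram-Lak kernel (optional Hann
apodization, off by default), FFT convolution, scaled by the radial
step so FBP is quantitative: a static disk's interior mu is recovered
to 0.1% (the acceptance bound is 2%).  Short-scan redundancy is handled
in the rebinned domain with a cos^2 taper over the `fan`-wide overlap;
conjugate weights are pairwise renormalized to sum to one exactly.

PAR images backproject one `fan`-wide wedge with uniform weight and the
global `dtheta` scaling — they are edge images for registration, not
quantitative reconstructions, and both PARs share the same scale.

## Motion estimation

Band-pass: isotropic radial raised-cosine mask, pass band `[0.1, 0.3]
pi` rad/sample interpreted as normalized digital frequency (Nyquist =
`1.0 pi`), DC removed exactly.  The transition width is 0.6 of each
cutoff.  The wide transition is a deliberate choice: with narrow
transitions the filtered PAR texture is nearly monochromatic
(wavelength ~10 mm at 250 mm / 256 samples), and for displacements near
a half wavelength SSD registration is bistable — a small isolated
structure can lock in with the opposite sign, which we observed
directly as a sign-flipped artery estimate.  The soft low edge retains
a weak sub-band anchor that breaks the tie while still removing DC and
the deep low-frequency shading.  Filter family and softness are
configurable.

Registration: cubic B-spline FFD, control spacings 14.4 / 7.2 / 3.6 mm
over three levels, each level seeding the next by evaluating the
coarser field at the new control positions.  Similarity is mean SSD
with analytic gradient, evaluated inside the inscribed FOV circle
(outside it short-scan data are not measured, and image-border sampling
would otherwise make the objective discontinuous).  Images are smoothed
per level (`sigma = spacing/4` in pixels) and renormalized to unit
standard deviation so the objective is well scaled at every level.  A
light bending-energy penalty (weight 0.01 on mean squared second
differences of the control lattice) regularizes the aperture-problem
directions that a 52 deg wedge cannot constrain.  Optimization is
L-BFGS-B, zero-initialized, deterministic, box-bounded at +-14.3 mm per
coefficient; evaluated displacements are additionally
magnitude-projected onto the 14.3 mm cap.  Registration direction is
fixed = first PAR, i.e. the field maps first-PAR positions to last-PAR
positions; the sign convention is carried through compensation and
validated by the known-motion oracle.

## Motion compensation

The linear-in-time model scales the single field:
`d_t(x) = alpha(t) d(x)`, `alpha = (t - t_target)/(t_end - t_start)`,
target defaulting to the PAR midpoint, so `alpha` spans +-0.5 (slightly
beyond for the window's outermost views, which precede/follow the PAR
centers by half a fan angle).  The dense field is evaluated once on the
reconstruction grid and scaled per row; scaling the dense field or the
B-spline coefficients is identical for a fixed basis.  Signed scaling
approximates the inverse field for pre-target views; the error is
second order in the displacement and its gradient, which the 14.3 mm
cap keeps small.  Warped sample positions falling outside the measured
radial range contribute zero.  With a zero field the compensated
backprojection is bit-identical to the plain one.

## Evaluation

MSSIM uses the standard Gaussian-weighted SSIM (11x11, sigma 1.5,
K1 = 0.01, K2 = 0.03) via scikit-image, with the dynamic range taken
from the reference ROI because HU images are not 8-bit; a hand-rolled
scalar implementation cross-checks it in the tests.  ROIs default to
20 x 20 mm around each artery.  RMSE is reported in HU over a mask.
Profile stability samples a line that lies inside the myocardial wall
band at *every* phase (truth is constant there, so pooled variation is
artifact) and pools samples across phases (population SD).  Paired
one-sided t-tests use scipy; zero-variance differences are handled
explicitly (p = 0.5 at zero mean, else 0/1 by sign).

## Problem sizes and runtime

The quantitative suite runs 6 pipeline cases (xcat_like at 60/80/100
bpm x R-R 30%/70%) on a 256^2 grid with 720 views/rotation and 736
channels — the package's reference discretization — yielding 18 ROI
pairs in about 20 s total on one CPU; the profile-stability experiment
reconstructs 5 phases x 2 methods in a similar time.  Simulations cover
only the gating window of each case (plus margin) on the absolute scan
lattice, which keeps cost proportional to what is reconstructed.

## What the synthetic experiments do and do not show

The phantom exercises the full algorithmic chain — time-resolved
projection, conjugate-PAR asymmetry, registration, linear scaling,
compensated backprojection — under exactly known ground truth.  It does
not emulate anatomical texture, contrast dynamics, spectral effects,
scatter, 3D/cone-beam geometry, respiratory motion, or irregular
rhythms.  Passing tests therefore demonstrate correctness of the
method's mechanics and its behavior under idealized cardiac-like
motion, not clinical performance.  Known limitations inherited from the
method itself: motion that is strongly nonlinear inside one window is
only partially corrected; displacement components along directions
invisible to a 52 deg wedge are fixed by regularization, not data; and
structures moving more than the cap between PARs are out of model
range.
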