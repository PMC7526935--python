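# parmoco

Partial-angle cardiac CT motion estimation and motion-compensated
reconstruction, with a dynamic analytic phantom for end-to-end testing.

## The problem

Cardiac CT reconstructs a beating heart from less than one gantry
rotation of data.  Even at 0.25 s/rotation the coronary arteries and
the myocardial wall move several millimetres inside one short-scan
gating window, producing blur, doubled edges, and HU bias that can mask
or mimic disease.  `parmoco` implements a segmentation-free motion
correction scheme that operates on a single short scan:

1. **Gating.** A contiguous window of tube angle `pi + 2*fan` (284 deg
   for the 52 deg fan used here) is centred on the view acquired
   closest to the target R-R phase.
2. **Rebinning.**  Fan rays (beta, gamma) are rebinned to parallel
   geometry, `theta = beta + gamma`, `s = R sin(gamma)`; the fully
   covered parallel span is the short-scan span `pi + fan`.
3. **Conjugate partial-angle reconstructions (PARs).**  The first and
   last `fan`-wide wedges of parallel rows are backprojected
   separately.  Their central view angles differ by `pi`, so they are
   acquired `rotation_time / 2 = 125 ms` apart: two time-resolved (if
   incomplete) snapshots of the moving anatomy.
4. **Band-pass + registration.**  Both PARs are band-pass filtered
   (radial pass band `[0.1, 0.3] pi` rad/sample) to keep edges while
   discarding limited-angle shading, then registered with a cubic
   B-spline free-form deformation (control spacing 14.4 -> 7.2 ->
   3.6 mm, SSD similarity, bending-energy penalty, 14.3 mm displacement
   cap).  The result is a motion vector field d(x) between the two PAR
   time points.
5. **Motion-compensated WFBP.**  Motion is assumed linear in time
   across the half rotation: a view at time t uses displacement
   `alpha(t) * d(x)` with `alpha = (t - t_mid)/(t_end - t_start)`.
   During the weighted (Parker-style) filtered backprojection each
   target-frame pixel is shifted by its view-specific displacement
   before the filtered row is sampled.

Everything runs on a 2D axial plane (the algorithm is slice-separable
for axial scans); the forward model is an analytic fan-beam projector
over a phantom of ECG-driven ellipses, annuli and disks, so the whole
chain is testable without any external data.

## Who it is for

Researchers prototyping motion-compensated CT reconstruction, and
anyone needing a self-contained, deterministic test bed for gated
reconstruction algorithms: dynamic phantom presets emulate a beating
heart (contracting wall annulus, chambers of different contrast, three
coronary-artery disks), a rotating coronary-rod phantom, and a
pulsating balloon phantom.

## Worked example

```python
import numpy as np
import parmoco as pm
from parmoco.fixtures import gated_timeline
from parmoco.metrics import mssim
from parmoco.phantom import ground_truth

geo = pm.SystemGeometry()                    # 52 deg fan, 0.25 s/rot
phantom = pm.preset("xcat_like", heart_rate=80)
grid = pm.ReconGrid(256, 250 / 256)          # 250 mm FOV

timeline = gated_timeline(geo, phantom.ecg, target_phase=0.7, cycle_index=1)
sino = pm.forward_project(phantom, geo, timeline)

fbp = pm.fbp_reconstruct(sino, phantom.ecg, 0.7, grid, cycle_index=1)
mc  = pm.sculli_reconstruct(sino, phantom.ecg, 0.7, grid, cycle_index=1)

gt = ground_truth(phantom, fbp.target_time, grid)
roi = pm.ROISpec(center=(44.0, -22.0), half_extent=10.0, label="rca")
print(f"RCA MSSIM  fbp {mssim(fbp, gt, roi):.3f}  corrected {mssim(mc, gt, roi):.3f}")
```

prints

```
RCA MSSIM  fbp 0.378  corrected 0.918
```

At 80 bpm and the R-R 70% phase the artery disk moves ~4 mm between the
two PAR time points; plain FBP smears it into a double image (MSSIM
0.38 against the motion-frozen ground truth), while the compensated
reconstruction restores it (0.92).  The same command-line flow is
`parmoco simulate`, `parmoco recon --method fbp|sculli`,
`parmoco estimate-motion`, `parmoco evaluate`, `parmoco demo`.

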