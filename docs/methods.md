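# Methods

`priorphase` implements markerless respiratory phase recognition for
rotational lung radiotherapy: a prior phase-resolved cone-beam CT (4D-CBCT)
is re-projected into template radiographs, and each in-treatment kV frame is
assigned a respiratory phase by normalized cross-correlation against the
templates at its gantry angle. Because no clinical data ships with the
package, every input is produced by a built-in 4D digital thorax phantom
whose ground-truth phase labels replace the human visual verification a
clinical study would use.

## Breathing model and phase convention

Quiet breathing dwells near end-exhale. The trace generator uses the
even-power cosine

    d(t) = A * (1 - cos^(2n)(pi t / T)),    n = 2 by default,

with `d` the cranio-caudal displacement (0 = peak exhale, `A` = peak
inhale). Defaults are `A` = 10 mm peak-to-peak and `T` = 4 s — typical
quiet-breathing values for lung patients; both are configuration, not
measurements. `irregularity` (default 0.1 on the benchmark) jitters each
cycle's period uniformly by up to +-10% and shrinks its amplitude by up to
10%, keeping displacement inside `[0, A]`.

The cycle is split into 10 equal-duration phase bins; phase 1 opens at the
peak-exhale anchor (displacement minimum) and phase 6 covers peak inhale.
This temporal (phase-angle) binning is the standard 4D-CBCT sorting;
amplitude binning was considered and rejected because phases are named by
their position in the cycle (early/mid/peak inhale and exhale), not by
displacement level. Labels are assigned per cycle between detected
anchors, with the first/last cycle extrapolated from its neighbor; samples
landing exactly on a bin edge belong to the later bin (a 1e-9 epsilon
guards the floating-point boundary).

A subtlety of the symmetric cosine model: mirror bins (2,9), (3,8), (4,7)
and (5,6) have nearly identical mean displacements (within 0.01–0.05 mm).
The per-phase volumes are rendered at the bin-mean displacement of one
noiseless cycle, computed by discrete sampling with left-closed bins so the
peak-inhale sample falls in bin 6 and phase 6 is the strict maximum.

## Phantom

The thorax is an ellipsoidal soft-tissue body (mu = 0.020 /mm), two
ellipsoidal lungs (0.004 /mm), a diaphragm dome (0.022 /mm) whose apex edge
sits inside one lung, and a spherical tumor (0.025 /mm, radius 10 mm)
inside the other-side lung volume, placed well clear of the dome so the two
structures never merge in a reconstruction. Tumor and dome translate
rigidly along the motion axis (default cranio-caudal, caudal on inhale);
body and lungs are static. Attenuation values are plausible soft-tissue /
lung contrast at kV energies, chosen for contrast rather than taken from
any measurement; everything is configurable through `PhantomSpec`.

Voxelization uses partial-volume ("soft-edge") rendering by default: each
boundary voxel blends the neighboring attenuations across a half-voxel-wide
transition band computed from an approximate signed distance to the
surface. This matters twice: it reproduces the partial-volume behavior of
real CT, and it makes the rendered volume depend *continuously* on
displacement. With hard binary membership, the sub-voxel displacement
differences between mirror phase bins rendered identical volumes, so
templates tied and phase recognition between mirror phases was undefined.
Binary rendering remains available (`soft=False`).

What the phantom does **not** emulate: deformation and hysteresis (motion
is rigid translation), cardiac motion, realistic anatomy texture
(XCAT-class detail), scatter, beam hardening and detector physics beyond
Poisson counting noise. Passing benchmarks therefore demonstrate the
correctness and internal consistency of the pipeline under controlled
conditions, not clinical accuracy on patients.

## Forward projection

Re-projection follows the Beer–Lambert line integral
`P_i = P_o exp(-sum_j a_ij f_j)` with `f_j` the voxel attenuation and
`a_ij` the **exact** intersection length of the source-to-pixel ray with
voxel j, computed by a Siddon-style parametric voxel walk (no interpolated
sampling). `trace_ray` exposes the per-voxel path; the detector-grid hot
path runs the same walk in a compiled (numba) kernel. Tests verify the
walk against analytic box-chord lengths (1e-6 mm) and a dense
midpoint-quadrature oracle (1e-3 relative).

Geometry: isocentric circular trajectory in the axial plane, gantry angle
theta placing the source at `(-sad sin(theta), sad cos(theta), 0)` (0 deg =
anterior), flat panel orthogonal to the source–isocenter axis at distance
`sdd`. Defaults sad = 1000 mm, sdd = 1536 mm with a 256x256, 1.6 mm panel;
benchmarks use a 128x128, 3.2 mm panel (identical field of view, 4x fewer
rays) and a 64^3, 3 mm reconstruction grid — the package's own desk-scale
problem sizes. Detector noise is Poisson resampling at a configurable
expected fluence per unattenuated pixel (default benchmark 1e5 photons),
standing in for in-treatment kV degradation such as MV scatter; it is a
noise model, not a physics simulation.

## FDK reconstruction

Standard flat-panel FDK: intensities are log-transformed to line integrals
(non-positive pixels clamped with a warning), rescaled to a virtual
detector through the isocenter, cosine pre-weighted, redundancy weighted
(1/2 on a full circle, generalized Parker weights with half over-scan
`delta = (span - pi)/2` on short scans), ramp filtered row-wise in the
frequency domain using the band-limited spatial-domain kernel (Hann
apodization on by default for noise robustness), and backprojected with
bilinear detector interpolation and the `sad^2 / U^2` distance weight.
Per-view angular weights use the trapezoid rule on the sorted angles, which
also handles the irregular per-phase angle subsets of phase-sorted
reconstruction. On the 64^3 uniform-sphere benchmark the reconstruction
correlates at ~0.99 with the truth inside the body and recovers the
absolute attenuation scale to a few percent.

4D reconstruction simply runs FDK per phase bin on that bin's projections.
With a 600-frame slow prior rotation (0.18 s/frame, ~27 breathing cycles)
each phase receives ~60 well-spread views; streak artifacts appear but the
thresholded tumor centroid still recovers the phase-1 to phase-6 shift to
a fraction of a voxel.

## Template bank and matching

Templates are re-projections of the 10 prior phase volumes at integer
gantry angles (1 deg steps, -180..+180 by default, or a declared subset
such as the planned treatment arc), cropped to a fixed detector ROI. The
default ROI is computed automatically as the union of the projected tumor
sphere over all treatment angles and displacements, dilated by 5 pixels —
the synthetic analog of outlining the anticipated tumor motion range.

Matching uses the textbook normalized cross-correlation (mean-subtracted,
variance-normalized), which is symmetric, bounded in [-1, 1] and invariant
to positive affine intensity maps; a constant image raises an error rather
than returning a number. Each frame is compared against the 10 templates
at the nearest integer angle (exact half-degree ties resolve toward 0 deg;
linear template-angle interpolation was considered and left out as the
nearest-degree bank already over-resolves a 1 deg/frame arc). Exact
correlation ties break toward the smallest cyclic distance to the previous
frame's phase — respiration moves in order — and then toward the lower
phase number.

Correlation is computed on log-transformed (line-integral) images by
default (`match_domain="log"`). Raw-intensity correlation is equivalent
for ideal templates, but with reconstruction-derived templates the
exponential amplifies reconstruction error in heavily attenuated lateral
views: on the benchmark, intensity-domain matching with FDK templates
dropped to ~72% in the visible window while log-domain matching held ~97%.
Log images are linear in attenuation, so reconstruction error enters
additively. Raw-intensity matching remains available.

## Match criteria and scoring

A recognized phase is scored against the ground-truth label with:

* **Two-phase criterion** — cyclic phase distance
  `min(|p - q|, 10 - |p - q|) <= 2`. The distance is cyclic because phases
  10 and 1 are both peak exhale and must count as a match.
* **Relative phase criterion** — applied only to frames failing the
  two-phase test (phases that "suddenly appear" out of respiratory order):
  the frame still counts as a match if the obtained phase's correlation is
  within 0.01 of the reference phase's correlation on the same frame,
  since mirror phases of the cycle show nearly identical tumor position
  and shape. The reference correlation is looked up in the same frame's
  10-phase correlation vector.

The evaluation driver restricts headline match rates to the tumor-visible
angular window (default -135 to -67 deg), where a human reference would
exist clinically; all frames are tracked and reported separately. The
Amsterdam-Shroud baseline is scored with the two-phase criterion only (it
produces no correlation values).

## Amsterdam-Shroud baseline

The shroud is built per the standard published description: log-transform
each projection, differentiate along the cranio-caudal detector axis, sum
absolute derivatives laterally, and stack one column per frame. Signal
extraction smooths each column (5-row window), selects the row band with
the largest temporal variance (half-width 20 rows), refines the per-frame
peak to sub-pixel precision by parabolic interpolation, converts rows to mm
at the isocenter, flips sign so caudal diaphragm motion (inhale) is
positive, detrends linearly and re-zeros at peak exhale. The extracted
trace is phase-labelled exactly like a ground-truth trace. Dominant-period
estimation zero-pads the FFT 8x and refines the magnitude peak
parabolically, giving sub-bin resolution on short series.

No specific vendor implementation is reproduced, and no baseline-drift
correction is applied. The baseline is sensitive to detector row pitch: at
the default 128x128 panel it tracks the true phase essentially perfectly
in noiseless conditions, while a 64x64 panel (half the rows over the same
field of view) degrades it below 60% — one illustration of why direct
tumor matching is preferable to a diaphragm surrogate.

## Numerical choices and degenerate inputs

* Ray walk: 1e-12 parametric epsilon; rays missing the volume return empty
  paths; a source inside the volume or a zero-length ray is an error.
* Ramp filter: zero-padding to the next power of two >= 2 x detector
  columns; filter response from the exact spatial kernel (avoids the DC
  bias of a pure |f| ramp).
* `log_transform` clamps non-positive (noise-floor) pixels to 1e-9 P_o
  with a logged warning.
* Phase bins with fewer than 3 projections reconstruct anyway with a
  warning; an empty bin is an error.
* Static scenes: the shroud extractor returns a zero-amplitude trace with
  a warning; phase labelling of a flat trace is an error.
* All randomness (trace jitter, Poisson noise) flows from explicit seeds;
  per-frame noise seeds derive from the experiment seed via
  `SeedSequence`, so runs are bit-reproducible.

## Known limitations

* The synthetic benchmark is an analog of the clinical study, not a
  reproduction: patient-specific accuracies depend on anatomy, scatter and
  reader variability that the phantom does not model, and the clean
  phantom makes both methods score higher than clinical figures.
* Rigid single-axis motion cannot probe deformation- or
  hysteresis-induced template mismatch.
* The Parker-weighted short-scan path assumes span >= 180 deg + fan;
  below that it warns and reconstructs with limited-angle artifacts.
* Matching latency is not benchmarked; the per-frame cost here (10 NCCs on
  a small ROI) is microseconds-to-milliseconds in numpy, but no real-time
  claim is made.
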