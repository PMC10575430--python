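# Methods

This note documents the models and procedures the package implements, the
synthetic scenes they are validated on, and the design choices made where
the underlying method description leaves the design open.

## Problem setting

In brain-slice patch-clamp experiments a glass micropipette, mounted at an
oblique angle, must touch the membrane of a chosen neuron gently enough to
seal but firmly enough to deform it.  Under a 40x water-immersion
objective the pipette never appears sharp as a whole — each point of its
tilted axis lies at a different depth — and in slice tissue the dent made
at contact is invisible among DIC shadows.  The pipeline therefore splits
the task into four detectors, each of which this package implements as a
library function with a synthetic-scene test bed.

## 1. Depth focusing by motion detection

Per-pixel gray values are modelled as a mixture of K Gaussians
(`motionfocus.MixtureBackgroundModel`, K = 3 by default, allowed 3–5).  A
pixel is foreground when its value lies further than `match_sigmas` = 2
standard deviations from every component; the matched component is pulled
toward the observation with `learning_rate` = 0.05, and where nothing
matches, the weakest component is replaced by a wide fresh one
(`sigma_init` = 15 gray levels).  Component weights are renormalised after
every update and standard deviations floored at `sigma_min` = 2 so the
match window never collapses.  The background image assembled from the
dominant components is differenced against the current frame and
binarised at `threshold_T` = 15 gray levels; the final moving-pixel mask
is the conjunction of the no-match flags and the binarised difference,
which makes the detector robust both to slow drift and to illumination
gain.

The clarity indicator of a frame is the rightmost image column occupied
by a connected moving blob of at least `min_blob_px` = 20 pixels,
normalised by image width.  Swept from below the tip upward, the
indicator is 0 while the focal plane is under the pipette and jumps to
the tip's abscissa the moment the plane reaches the tip, giving a
step-shaped curve.  The step rule is explicit: the declared tip plane is
the first frame of the first run of `consecutive` = 3 frames whose
indicator is positive and at least `step_fraction` = 0.5 of the running
maximum; the first 5 frames only train the background model.  Whether
the original indicator is the maximum, mean or centroid abscissa of the
moving pixels is not documented; the maximum is used because the tip is
the rightmost structure that can move, and the curve is normalised by its
maximum because no other normalisation is specified.

## 2. Scanning-line tip localization

Inside a detector-supplied ROI (tube to the left, pure background right
of the tip) vertical scanning lines are visited right to left.  The
reference value is the 95th percentile of the per-column minima over the
rightmost 20% of columns — a pure-background strip; the percentile keeps
small dark impurity specks from dragging the reference down.  The first
column whose minimum falls below `rel_threshold` = 0.8 of the reference,
with at least 2 qualifying pixels (speckle guard), is the tip's
x-coordinate; the mean row of that column's qualifying pixels is the
y-coordinate.  Because the cutoff is relative, the estimate is invariant
to global illumination gain, and it is equivariant under ROI translation
by construction.  The bounding-box-centre baseline is retained for
comparison; detector boxes stretch leftward over the taper, which is
exactly why their centres are biased by tens of pixels.

## 3. Neuron 3D fusion

Per-plane detections (any producer of `Box2D`; the bundled oracle
detector jitters ground-truth ellipse boxes with sigma = 1 px) are grouped
transitively when they overlap by at least 60% and lie within 2 um in
depth.  Overlap is intersection-over-union; intersection-over-smaller is
available via `overlap_mode` since the original measure is not named.
Groups are split where consecutive member planes gap by 2 um or more
(one neuron cannot skip planes), and groups whose thickness — depth span
plus one z step — does not exceed 3 um are discarded ("more than 3
sequential images" is read strictly as >= 4 member planes at the 1 um
step).  Surviving groups become a `Box3D` with union xy extent; the
optimal focus height is the middle of the depth interval, where an
ellipsoidal cell's cross-section is maximal.  Single-link grouping is
used rather than clique grouping because boxes accumulate plane by
plane; both choices agree on all bundled scenes.

## 4. Defocus network

`cunet.CuNet` is a small multi-task U-net operating on a 128x128 ROI:
with the target cell at (cx, cy), the crop spans 256 px to the left
(taper side) and 128 px right/up/down — 384x256 — and is resized
bilinearly.  A shared encoder (depth 4, base 8 channels, 3x3
convolutions, 2x2 max pooling) feeds (a) a nearest-upsampling decoder
with skip connections ending in a 1x1 convolution that predicts the
binary pipette mask, and (b) a regression stack on the bottleneck — 3x3
convolution, global average pooling, a fully connected layer and a
sigmoid — that outputs the defocus degree, the tip's distance from the
focal plane mapped linearly from 0–10 um onto 0–1.  Training minimises
`0.5 * BCE(mask) + 1.0 * MSE(defocus)` with Adam (learning rate 2e-3,
batch 8, 10 epochs, all seeded).  Inputs are standardised per image
(zero mean, unit variance): the ROIs are dominated by flat background,
and without the normalisation the regression head stalls at the label
mean.  The forward and backward passes are written directly in numpy
(im2col convolutions over BLAS, float32), which keeps training on one
CPU core at about half a minute per epoch for ~500 samples and makes
runs bit-reproducible on a given machine.  Capacity was chosen as the
smallest that passes the recovery checks (held-out defocus MAE <= 0.1,
mask Dice >= 0.8); a depth-3 encoder plateaus near Dice 0.7.

## 5. Contact state machine

The bath resistance (baseline) is the median of the first 10 trace
samples after solution entry.  During descent the defocus network is
evaluated only while the quantised resistance rise lies in
[`arm_delta_r`, `max_delta_r`] = [0.1, 0.5] MOhm; contact is declared at
the first armed frame whose defocus degree drops below 0.2.  Crossing
the ceiling without a visual trigger, or reaching the end of the stream,
yields `no_contact_window_exceeded`.  Evaluation pauses (rather than
stops) if the rise falls back below the arm level.  One source states
the window as [0.2, 0.5] MOhm; 0.1 is adopted as the majority reading
and the window is configurable.  Frames are joined to the trace by
nearest sample with a tolerance of one frame interval; larger skew is a
hard error.  Pipette qualification accepts a baseline inside a closed
interval (default 3–8 MOhm), prescribes one positive-pressure blow on
the first violation and replacement on the second.

## The synthetic scenes

The generator (`synthscene`) is the package's test bed and defines the
study conditions; every artifact carries its exact ground truth.

* **Pipette.**  Two dark converging walls (3 px thick, gray 90 on
  background 180) flank a dimmer lumen (half-gap 2 px at the tip, growing
  0.08 px per pixel leftward); over the last 6 columns an extra-dark core
  ramps in, graded by 18 gray per row off-axis, so the tip column shows a
  single valley flanked by two sub-background bands.  The axis climbs
  leftward at 25 degrees; pixels are 0.2 um.
* **Depth appearance.**  A point at offset d = focal_z − z_point is drawn
  with Gaussian blur sigma = `blur_per_um` * |d| (default 1.2 px/um) and
  contrast fading linearly to zero over `vis_range_um` = 15 um for d >= 0
  and over `vis_range_above_um` for d < 0.  The focusing-stage default
  `vis_range_above_um` = 0 hides the pipette completely until the plane
  reaches the tip — frames below the tip are bit-identical at zero noise,
  which is the observed no-motion-before-focus phenomenology and what
  makes the clarity step sharp.  Contact and tip-ROI scenes use 18 um so
  the approaching tip stays visible with blur encoding its distance.
  `blur_per_um` = 0 switches the depth model off (the analytic limit used
  by pixel-level tests).  A smooth symmetric profile cannot reproduce the
  exact below-tip stillness; the asymmetry is the one deliberate
  idealisation of the renderer.
* **Neurons.**  Ellipsoids (semi-axes ~3–5 um) darker than background by
  45 gray; the cross-section exists strictly inside |z − cz| < c and
  peaks at mid-depth.  Impurities are the same blobs with depth semi-axis
  <= 1.5 um, so on the 1 um grid they appear in at most 3 planes and the
  thickness rule rejects them by construction.
* **Resistance.**  Constant at the bath value until the tip passes the
  contact height, then rising proportionally (0.15–0.3 MOhm/um); 62.5%
  of sequences plateau after a sampled rise of 0.2–0.45 MOhm and 37.5%
  keep rising, matching the reported split.  All values are rounded to
  the 0.1 MOhm measurement grid.
* **Noise and illumination.**  Additive Gaussian noise (sigma 3 gray)
  keyed by (scene seed, focal plane) so renders are bit-reproducible;
  brightness gains {0.6, 0.8, 1.0, 1.2} emulate the four illumination
  levels of the robustness sweep.

What the scenes do *not* model: DIC physical optics, tissue texture and
occlusion, vibration, stage drift, electrode noise spikes, or giga-seal
electrophysiology.  Passing the bundled bounds therefore demonstrates
the correctness and internal consistency of the algorithms under the
stated assumptions — not their accuracy on real slices, which the
original system validates with hardware.

## Problem sizes and numerics

Desk-scale defaults keep every check on one CPU core: focus stacks are
320x320 px x 51 planes; the accuracy sweep uses 10 stacks x 4 gains; tip
accuracy uses 50 ROIs; the defocus network trains on 45 cells x 11
defocus levels = 495 ROIs for 10 epochs (~6 min) and is exercised on 8
descents.  Degenerate inputs raise typed errors (`InvalidSpecError`,
`FormatError`, stage errors) rather than propagating NaNs; box areas and
overlap are computed in float with half-open conventions; the defocus
output is clamped to [0, 1]; mask probabilities are thresholded at 0.5.

## Known limitations

* The pipette appearance is calibrated only to its qualitative
  description; absolute gray levels and widths are free parameters.
* The CU-net is trained and evaluated on the same renderer family
  (held-out cells, seeds and scenes, but the same generative model); no
  claim is made about transfer to real imagery.
* The resistance model is noise-free by default; the planned filtering of
  measurement spikes (adaptive derivative estimators) is out of scope.
* Hardware control (manipulator, pump, stage) is replaced by schedule
  replay; timing jitter between camera and amplifier is modelled only as
  the nearest-sample join tolerance.
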