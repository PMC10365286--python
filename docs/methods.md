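# Methods

This note documents the models implemented in `pulmo3d`, the choices made
where the method description leaves the design open, and what the
phantom-based experiments do and do not demonstrate.

## Problem setting

Automatic pulmonary-nodule detection on chest CT proceeds in two stages: a
detector proposes candidate nodules `[x, y, z, d]` with confidence scores,
and a false-positive-reduction classifier removes candidates that are
actually normal tissue (most often vessels, whose axial cross-section
resembles a nodule on any single slice). Performance is summarised by FROC
analysis — sensitivity as a function of false positives per scan — and by
the CPM, the mean sensitivity at 1/8, 1/4, 1/2, 1, 2, 4 and 8 FP/scan.

## Preprocessing

CT intensities are windowed from Hounsfield units to gray: `g =
clip(round(255 * (h + 1200) / 1800), 0, 255)` with round-half-up (the
rounding rule is fixed for reproducibility; the window is [-1200, 600] HU).
Volumes are resampled to 1 mm isotropic spacing with trilinear
interpolation; output size per axis is `round(extent / 1 mm)` so physical
extent is preserved to within one voxel. Lung masking is the classical
pipeline — Gaussian smoothing (sigma 1), low-density thresholding,
exclusion of border-connected air, retention of the two largest interior
low-density components, morphological closing, intersection with the filled
body envelope. The low-density threshold defaults to 110 gray, the midpoint
between parenchyma (~50) and soft tissue (~170) on the windowed scale.
Masking zeroes non-lung voxels rather than cropping (a crop flag exists);
detection runs with or without the mask.

## Rotation pretext task

Each volume is rotated in the axial plane by 0/90/180/270 degrees; a
classifier (the detector backbone plus two fully connected layers) predicts
the rotation. The loss is the mean negative log-probability assigned to the
true class over the K = 4 rotated copies. The rotation convention is fixed
as 90 degrees mapping `(y, x) -> (x, H-1-y)`; the transform is an exact
voxel permutation, so the pretext dataset is exactly class-balanced by
construction. Backbone weights transfer verbatim into the detector because
both networks build the backbone from the same configuration.

The reference-scale schedule (lr 0.1 halved after epochs 70 and 85, weight
decay 5e-4, 100 epochs, batch 16) ships as `RotationTaskConfig.reference()`;
the desk-scale run (`.desk()`: lr 0.02, 20 epochs) trains on 32-voxel chest
phantoms in about two minutes on one CPU core.

## Detector

The detector is a densely connected 3D feature pyramid over a
ResNet-style bottom-up backbone (stem at full resolution, four stride-2
stages C2..C5). All four stages are projected to a common width by 1x1x1
lateral convolutions, and *every* pyramid level P2..P5 sums contributions
from *all four* laterals: coarser sources are upsampled by learned
block-transposed convolutions (kernel = stride = the scale factor), finer
sources are max-pooled down. Each active level carries a 3x3x3 conv tower
and two sibling 1x1x1 convolutions predicting per-anchor objectness and
box offsets `((dz, dy, dx)/side, log(d/side))`.

Anchor cubes of sides {3, 5, 10, 15, 20, 25, 30} voxels tile the levels by
receptive-field scale ({3,5} on P2, {10,15} on P3, {20,25} on P4, {30} on
P5). Assignment: IoU < 0.02 negative, IoU > 0.4 positive, the band between
ignored; additionally the best-overlapping anchor of each ground-truth cube
is forced positive (without this, a nodule whose diameter falls between two
anchor sides — e.g. 7 voxels against anchors 5 and 10, max IoU ~0.36 —
receives no positive anchor at all). Ground-truth nodules are represented
as cubes of side d for IoU purposes.

Training supervises every non-ignored anchor with class-balanced binary
cross-entropy (positive class weighted by the negative:positive count
ratio) plus smooth-L1 regression on positives. Dense supervision is the
load-bearing choice here: sampling a few dozen negatives per step out of
~70k anchors leaves most positions unsupervised and the objectness head
collapses to a near-constant output; supervising all anchors is equally
cheap (one vectorised pass) and converges cleanly.

Inference tiles the volume with 96-voxel windows overlapping by 32 voxels
(overlap ≥ the largest nodule, so no nodule is split by every window
boundary; edge windows are clamped and zero-padded), keeps boxes with
objectness probability above 0.1 (applied before NMS), caps each window at
its 300 highest-scoring boxes, maps detections to world millimetres and
merges them with greedy 3D NMS at IoU 0.1 (ties broken by input order).
Cross-window merging uses a responsibility rule: each window reports only
detections whose centre lies in its central region (half the overlap as
margin, relaxed at the volume border), so a nodule in an overlap zone is
claimed by the single window that sees it with the most context — windows
that see it near their padded edge localise it poorly. NMS additionally
suppresses a candidate whose detection sphere intersects a kept
candidate's (centre distance below the sum of radii): same-nodule
duplicates from neighbouring anchors can disagree in box size enough to
slip under the IoU threshold, while two genuinely distinct nodules have
disjoint spheres.

Two further numerical choices: the objectness bias is initialised to -2 so
early training is not swamped by the background class, and after the last
epoch the batch-norm running statistics are re-estimated by one cumulative
averaging pass over the training windows — desk-scale runs are far too
short for momentum-averaged statistics to converge, and stale statistics
visibly corrupt eval-mode predictions.

`DetectorConfig.tiny()` (64-voxel windows, anchors {3, 5, 10}, 8 pyramid
channels, backbone widths (4, 8, 16, 16, 16) with no residual blocks, 25
epochs at lr 0.02) trains on 30 phantoms in about four minutes on one CPU
core. The full-geometry configuration (96-voxel windows, 64 channels, all
seven anchors) is exercised for its architectural contract — stage sizes
96/48/24/12/6 cubed and 64-channel pyramid levels — not trained at desk
scale.

## Location history images and HS2

The LHI is a per-pixel decaying record of supra-threshold slice-to-slice
intensity change: scanning an 11-slice stack (5 slices each side of the
candidate slice), a pixel whose absolute difference between consecutive
slices exceeds the threshold resets to tau = 10; otherwise it decays by 1,
floored at 0. `f` is initialised to zero before the first pair. Nodules —
discs expanding then contracting concentrically as a sphere crosses slices
— produce compact, centred LHI patterns; vessels — discs translating
laterally — leave displaced streaks. Two thresholds (30 and 40 gray) yield
two patches per candidate as augmentation. The patch is cropped at twice
the candidate diameter in y and x (zero-padded at borders), the LHI is
computed on the raw crop (thresholds are defined on raw gray differences,
so the resize comes after), then resized to 48x48 with bilinear
interpolation and no re-quantisation.

HS2 is a small CNN over these patches: valid 5x5 convolutions with 30 and
50 channels (each followed by ReLU, batch norm and 2x2 max pooling) and
fully connected layers 2048/1024/512 into a two-way softmax. The tissue
class is undersampled to within one sample of the nodule count;
augmentation applies random flips, 90-degree rotations and 0.9-crops.
At inference the probabilities of a candidate's patches are averaged;
p >= 0.5 keeps the nodule label, below it the candidate is relabelled
tissue and dropped from the positive set (raw scores and coordinates are
never modified). The desk default of 15 epochs is used because the loss
plateaus within ~10 epochs on phantom patches; the reference schedule
(2000 epochs, lr 0.01 divided by 10 every 500) is kept in the config as
`epochs_reference`.

In the end-to-end experiment HS2 trains on the detector's own training-set
candidates, labelled nodule/tissue by whether they hit a ground-truth
nodule, and extracted through the identical LHI path used at filtering
time. Training it on simulated sequences instead fails outright (the
filtered sensitivity drops to zero): the synthetic patch geometry does not
match the inference-time distribution. The simulated sequences remain the
right tool for the isolated discrimination experiment, where train and
test come from the same generator.

## Evaluation

Matching follows the LUNA16 convention: a candidate hits a nodule if its
centre lies within the nodule radius; the highest-scoring hit is the true
positive, further hits are ignored (neither TP nor FP), non-hits are false
positives. Sensitivity at an FP level is the best sensitivity over score
thresholds whose FP/scan does not exceed the level (step-function reading,
no interpolation). CPM is the arithmetic mean over the seven levels,
reported at three decimals. Size-stratified CPMs partition nodules into
small [3, 5), medium [5, 10] and large (10, inf) mm — 5 mm belongs to
medium — with per-stratum sensitivities against stratum truths only while
the FP axis uses all candidates; an empty stratum reports None. The FROC
implementation is verified bit-for-bit against an independent oracle that
re-matches the candidate lists at every threshold.

## Phantom generator

The generator renders grayscale chest-like volumes in [0, 255]: optional
elliptical body wall (gray ~170) with two enclosed low-density lung fields
(~50), a bright posterior spine marker (~220) that breaks rotational
symmetry for the pretext task, spherical nodules (3-30 mm, additive
contrast ~120, antialiased over one voxel, cross-section following the
circular-cap profile `r(s) = sqrt(max(0, R^2 - (s - s0)^2))`), and
vessel-like z-axis tubes (radius 1.5-2.5 mm, contrast ~100) whose
cross-section drifts laterally 1-3 voxels per slice. Noise is i.i.d.
Gaussian, sd 8 gray, clipped to [0, 255] — the simplest model that
exercises the LHI difference thresholds. All randomness flows through one
seed; the returned annotation list is exactly the rendered nodules.

Study conditions for the desk-scale experiments: detection phantoms are
64-voxel cubes at 1 mm with 1-3 nodules of 4-12 mm and 2-4 vessels; the
pretext task uses 32-voxel chest phantoms; candidate sequences use 11
slices with disc radii 4-10 px. These conditions were fixed once, before
the experiments were run.

What phantoms do not emulate: anatomical texture, scanner artifacts,
juxtapleural and ground-glass nodules, vessel branching and curvature, HU
calibration differences between vendors. Passing the phantom experiments
demonstrates that the mechanisms work — the architecture trains, the LHI
separates the two motion patterns, filtering removes false positives
without sacrificing sensitivity — not that clinical-scale sensitivity
numbers transfer.

## Known limitations

* Pure-numpy training is practical only at the desk scale; the reference-scale
  configurations are shipped and type-checked but not trainable in
  reasonable time on one CPU core.
* Axis-aligned volumes only; direction cosines other than identity are
  rejected rather than resampled.
* Determinism is guaranteed for a fixed seed under single-threaded
  execution; multi-threaded BLAS may reorder reductions.
* The bootstrap confidence intervals of the LUNA16 evaluation and
  cross-validation bookkeeping are out of scope.
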