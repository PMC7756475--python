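# Methods

This note documents the models and procedures implemented in
`spinelabel`, the conventions chosen where the design was genuinely open,
and what the synthetic tests do and do not establish.

## Coordinate conventions

All volumes are `(SI, AP, LR)` arrays with 0-based indices, voxel-center
world coordinates in mm (`world = origin + index · spacing`), and
half-open crop intervals.  SI index grows superior→inferior, AP index
anterior→posterior, LR index left→right.  One stated convention package-
wide avoids silent axis flips between modules.  All file outputs carry
world millimetres, never voxel indices.  NIfTI I/O transposes to the
`(LR, AP, SI)` on-disk order with spacing in the header.

## Spinal-canal preprocessing

* The centerline is the per-axial-slice center of mass of the canal mask,
  in mm.  Slices with an empty mask between populated neighbours are
  filled by linear interpolation (a choice — the handling of empty
  predictions is not otherwise determined); no extrapolation beyond the
  populated range.
* The VOI is a per-slice square window of `cross_section_px` (default
  55) pixels centred on the nearest voxel to the centerline: 27 px each
  side at the default; for even sizes the extra pixel goes anterior/right
  (the alignment is a convention, only the size is prescribed).  The
  anterior-constrained variant keeps columns up to and including the
  slice centroid's AP index, which removes posterior processes from the
  projections.
* The reference canal segmenter is a deliberately small 3-layer
  convolutional net (Dice loss, Adam) with a contract, not an
  architecture target: on held-out phantom slices the predicted-mask
  centroid must land within 2 voxels (mean) of truth.  It is pluggable —
  any callable slice→mask, or precomputed masks, can replace it.  Exact
  replication of a full encoder–decoder canal segmenter is out of scope.

## Custom intensity projections

`x = w·AIP(VOI) + MIP(VOI) + (w−2)·MIP(VOI~)` with `w = 2` by default,
so the complement term vanishes and the image depends only on VOI
voxels.  Numerical choices:

* HU are clipped to the normalization window and scaled to [0, 1]
  **before** projection.  This makes the MIP insensitive to implant HU
  beyond the window's upper bound, which is the stated motivation for the
  combined projection; the alternative (normalize after projection) would
  let implants dominate.
* The combined image is min–max rescaled to [0, 1] (input stability; the
  order of operations after combination is otherwise unconstrained).
* Columns containing no VOI voxel are defined as 0 and logged, not
  errors.
* The three default window variants are `(−1000, 1600)`, `(−200, 800)`,
  and `(−200, 800)` anterior-constrained.  The specific winning windows
  of the original selection procedure are not published; these are
  plausible wide/bone windows, configurable and logged.  The published
  window-grid augmentation count is arithmetically ambiguous, so no
  fixed augmentation count is asserted anywhere.
* Images are zero-padded onto a 608×192 canvas (per view), content
  centred on the SI axis.  Geometry objects record the content box so
  pixel↔mm round-trips are exact (the origin is never rewritten, which
  would introduce float error).  The canvas SI capacity in mm follows
  from `canvas_rows × SI pixel pitch` and is logged, not asserted against
  any external figure.

## Gaussian labels

Each of the 26 anatomical channels holds an isotropic 2D Gaussian at the
projected truth centroid with σ = 2 px, **peak-scaled to 225 intensity
levels**, thresholded **strictly above 75**, Boolean; channel 27 is the
complement of the union.  Peak-scaling is the only reading under which a
75 cut yields a finite blob (the bare normal-density prefactor never
reaches 75); the strict inequality is a fixed tie-break.  The resulting
blob radius is `σ·√(2 ln(225/75)) = √(8 ln 3) ≈ 2.96 px`, which keeps
adjacent labels disjoint at ≥ 18 mm spacing on 2.5 mm/px sampling.

## Network

Per arm: four residual encoder stages at (32, 64, 128, 256) filters, a
shared bottleneck of three stages (512, 1024, 512) operating on the
concatenation of both arms, four decoder stages with skip concatenation,
and a 5×5 output convolution to 27 sigmoid channels.  All kernels 5×5
except the 2×2 stride-2 down and transpose convolutions; no pooling, no
dropout.  Conventions chosen where the block internals are unspecified:

* unit order conv → batch norm → PReLU;
* residual block = two such units plus an identity skip (1×1 projection
  when channel counts differ), no activation after the addition;
* batch-norm after the down/up convolutions as well;
* the null channel is supervised in both loss terms (nothing says to
  exclude it).

Loss: per view `(1 − soft Dice) + mean binary cross-entropy`, summed over
the two views.  Dice enters as `1 − 2Σpy/(Σp+Σy)` computed jointly over
all channels (a raw similarity added to CE would reward bad fits).
Training: Adam, batch 8, lr 2·10⁻⁴, seeded and fully deterministic.
Transfer learning: divide the learning rate by 100 (→ 2·10⁻⁶), two
epochs, no layers frozen, then ensemble.

**Engine.**  The runtime environment provides no deep-learning
framework, so the package includes a minimal numpy autograd
(`spinelabel.nn`): im2col+BLAS 5×5 convolutions, exact non-overlapping
2×2 strided/transpose convolutions, batch norm, PReLU, sigmoid, fused
Dice+CE loss, Adam.  Gradients are verified against finite differences
in the test suite.  Everything is float32.

**Reduced preset.**  `XNetConfig.reduced_preset()` uses a 96×32 input,
filters (4, 8, 16, 32)/(32, 64, 32), and lr 1·10⁻³.  The published
configuration is ~108× larger in parameters; the preset exists so a full
train/evaluate cycle runs in minutes on one CPU core.  The desk-scale
training schedule (`demo.train_reduced_model`) warm-restarts Adam every
5 epochs: with this tiny model the accumulated second-moment estimate
otherwise shrinks effective steps long before the heatmaps sharpen, and
periodic restarts restore progress at no extra cost.

## Decoding and ensembling

Raw per-arm outputs of the projection variants are summed element-wise
and values ≤ 1.0 zeroed (strict threshold).  A consequence worth noting:
a single sigmoid-range output can never pass the 1.0 threshold, so
decoding requires ≥ 2 variants or a lower threshold — documented, not
"fixed".  Per channel, the coordinate is the center of mass of the
connected component containing the global maximum; ties between equal
maxima break toward the superior position.  A level enters the 3D output
only if present in **both** views (conservative false-positive control;
one-arm behavior is otherwise undefined), with SI the mean of the two
views and AP/LR from the sagittal/coronal view respectively.  Ensembles
vote: a level is present iff a strict majority of members predict it;
coordinates are component-wise medians (the median of an absent value
being undefined).

## Evaluation metrics

TP requires 3D error < 20 mm (strict) *and* being the nearest prediction
to the truth centroid; a prediction failing either criterion counts as a
false positive **and** the level's truth as a false negative; levels
absent from both sides are true negatives, counted per absent channel of
the 26 (the only countable reading of "correct null predictions").
`F1 := 0` when `P + S = 0`; patient localization error is reported absent
when there are no TPs.  Region groups are cervical 1–7, thoracic 8–19,
lumbar 20–24, sacral 25–26 (the printed grouping overlaps at 24, which is
L5 in a 24-vertebrae layout, so the sacral range is corrected to 25–26).
"%passing" marks a patient passed iff every truth level in the clinically
viable region — truth order minus three levels at each end — is TP;
patients with fewer than seven levels have an empty region and are
excluded with a warning.

## Spacing QA

`S_i` is the distance between consecutive predicted bodies in anatomical
order (junctions spanning absent channels are kept and reported as gap
junctions), and `δ_i = |S_{i+1} − S_i|`.  The absolute value is a
deliberate reading: the printed difference formula is signed, but
detecting bodies "too close together or too far apart" requires
magnitude.  A scan is flagged iff any δ in a gating frame strictly
exceeds the threshold (default 10.1 mm); the sagittal frame gates by
default and all three frames (3D, sagittal, coronal) are always computed
and reported.  ROC analysis evaluates the flag over a threshold grid;
AUC is the trapezoid over the (FPR, TPR) staircase (equal to the
Mann–Whitney rank statistic on per-case max-δ scores, a tested
invariant), and the reported operating point maximizes Youden's J — the
original operating-point selection rule is unpublished, so Youden is this
package's choice.  Junction-count normalization across gap junctions is
not applied; such junctions are flagged explicitly instead.

## The phantom generator

`generate_phantom` renders vertebral bodies as bright (≈450–900 HU)
cuboid blocks whose centers are the truth centroids, spaced along the
arc of a curved canal by a configurable per-junction profile (default
≈18 mm cervical rising to ≈32 mm lumbosacral — the published material
shows the widening trend but prints no table, so the defaults are a
choice); posterior-process blocks behind the canal; a soft-tissue
elliptical body in air; Gaussian HU noise; optional ≥3000 HU implant
rods, an anterior contrast tube, and L6/T13/four-lumbar anomalies.
Anomalous bodies carry the adjacent standard name plus an anomaly flag —
they get no channel of their own, matching the fixed-26-channel label
space — and `emulate_fixed_channel_prediction` reproduces the
characteristic failure of such a labeler (lumbar names anchored to the
sacrum, leaving one junction spanning two physical gaps; four-lumbar
spines relabel seamlessly and are undetectable by spacing, a known
limitation).  `sample_cohort_configs` adds per-phantom jitter: ±8% on
junction spacings, curvature amplitude drawn per scan, per-phantom
seeds.

What the phantom does **not** emulate: realistic bone texture and
trabecular structure, ribs, partial-volume effects, metastatic lesion
appearance (no quantitative description is available; optional HU
dropouts only), scanner artifacts, or patient positioning variation.  A
green end-to-end test therefore establishes that the pipeline's
machinery — projections, labels, network, decoding, metrics, QA — is
internally consistent and learnable, not that clinical-cohort accuracy
figures transfer.

## Known limitations

* Clinical headline numbers (canal error 0.339 ± 0.299 mm, final-test IR
  94.2%, QA sensitivity/specificity 67%/95%, benchmark IR 91.3%) are not
  reproducible here: they require private cohorts or external downloads.
* The numpy engine is CPU-bound; the published configuration is
  practical for inference (seconds per forward pass) but not for
  full-scale training.
* DICOM input is not supported (no DICOM library in the target
  environment); volumes enter as NIfTI.
* Four-lumbar anatomy is undetectable by the spacing flag by
  construction.
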