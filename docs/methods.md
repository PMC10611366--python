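# Methods

## The measurement problem

Cortical bone thins at the base of the mandible as bone mineral density
falls, which makes mandibular cortical thickness on CBCT a candidate
screening marker for osteoporosis. The package implements a three-stage
pipeline that turns a CBCT volume into a cortical thickness estimate:

1. **Slice selection.** A residual classification network scores every
   axial slice with the probability that it is the "correct" slice — the
   one on which both mental foramina are visible. The argmax slice is
   passed on; in labelling practice a band of one or two neighbouring
   slices is also acceptable, so evaluation reports both per-slice
   accuracy and the per-volume *slice-hit* rate (selected slice inside the
   labelled band).
2. **Landmark regression.** A second residual network with a 14-output
   linear head places 7 landmarks on the selected slice: 5 points tracing
   the mandibular bone line (left to right) and the 2 canal/foramen
   points. Outputs are raw pixel coordinates, flattened (x1, y1, ..., x7,
   y7).
3. **Thickness measurement.** The 5 bone-line points define a polyline;
   orthogonal cuts are made at stations derived from the canal points, the
   resulting cross-sections are binarized, and a deterministic
   boundary-pair column scan measures the cortical run length in pixels.
   Millimetres follow from the voxel size (0.3 mm isotropic for the
   reference acquisition, hence 1 px = 0.3 mm).

Stages are deliberately modular: each has its own training target and its
own failure mode, and the pipeline wraps every stage so that an error is
reported against the stage that produced it rather than surfacing as a
silently wrong thickness.

## Network architecture and training

Both networks share the same *stem surgery*: the first convolution takes a
single grayscale channel (1 -> 64 channels, 7x7 kernel, stride 2, padding
3, no bias), and the classifier head is Linear(features, 512) / ReLU /
Dropout(0.2) / Linear(512, 2) / softmax. The regressor head is identical
except the final layer is Linear(512, 14) and there is no softmax.

Two backbone depths sit behind one switch:

* `full_101` — the 101-layer bottleneck network (3-4-23-3 stages, 2048
  features, global average pooling). Provided for realistic runs; it is
  not exercised in training tests because its depth buys nothing on 64x64
  phantoms.
* `small` — the same stem followed by one basic residual block and
  **global max pooling** (64 features). Max pooling is a deliberate
  choice: the discriminative structures in this task (the ~2 px canal
  voids, thin cortical edges) are small and local, and averaging over the
  8x8 feature map dilutes them below what plain SGD at a fixed small
  learning rate recovers. With max pooling the slice classifier converges
  within roughly twenty epochs; with average pooling it sits at the majority-class
  rate.

Training follows the stage conventions: the classifier minimizes
cross-entropy with plain SGD (lr 0.001, no momentum), the regressor
minimizes the mean absolute coordinate error (L1, in px) with Adam
(lr 0.001). Two pragmatic choices on top:

* **Class balancing.** Only ~15% of slices are positives (valid band of
  halfwidth 1 in a 20-slice stack). Each classifier epoch trains on all
  positives plus an equally sized fresh subsample of negatives; without
  this, SGD at lr 0.001 settles on the all-negative solution. The source
  protocol does not state its sampling; this is the package's choice.
* **Best-epoch weights.** Accuracy/L1 peak at some epoch and then
  oscillate (the per-epoch negative resample adds variance), so training
  keeps the weights of the best validation epoch — the same quantity
  ("maximum accuracy at epoch N", "minimum loss at epoch N") that this
  kind of experiment conventionally reports. Both behaviours are
  config-switchable (`balance_classes`, `keep_best`).

The loss plumbing avoids a known incoherence in the stage definitions: a
cross-entropy criterion applied after an explicit softmax layer
(double-softmax), and a cross-entropy criterion named for a coordinate
regression. The classifier trains on the negative log of the softmax
probability (gradient identical to cross-entropy from logits); the
regressor trains on L1, which is also the metric it is evaluated with.

All randomness flows from explicit integer seeds (weight init, shuffling,
dropout, phantom sampling); identical seeds reproduce identical volumes,
weights and reports bit-for-bit.

## The phantom generator

The patient CBCT data behind the original study are private, so training
and evaluation run on synthetic mandible phantoms with known ground truth.
A phantom is an axial stack (default 20 slices of 64x64, 0.3 mm/px
spacing) containing:

* a horseshoe-shaped bone band (open ring spanning 240 degrees): two
  concentric **cortical walls** of radial thickness `cortical_thickness_px`
  (default 4, the quantity under study) enclosing a **trabecular band**
  (default 6 px wide) of lower intensity, centred on `arch_radius_px`
  (default 19);
* two circular **canal voids** (default radius 2 px) piercing the outer
  wall at +/-62 degrees from the arch midline — the geometric stand-in for
  the mental foramina — present **only** on the valid band of slices
  (correct slice +/- 1 by default, configurable 0-2);
* a mild taper (arch radius shrinks 1.5% per slice away from the correct
  slice), so the stack narrows like an anatomical structure;
* additive Gaussian noise (default sd 0.02 against intensities of
  background 0.0 / trabecular 0.35 / cortical 1.0).

Ground truth records the valid band, the 5 bone-line points (equally
spaced along the outer-wall midline over +/-100 degrees), the 2 canal
centers, and the wall thickness. The canal angle (62 degrees) is chosen so
the voids stay clear of the +/-50-degree bone-line points; an earlier
draft at 55 degrees let small arches place a landmark inside a void,
violating the truth contract.

What the phantom does **not** emulate: CBCT projection physics
(beam hardening, scatter, metal artifacts), trabecular texture, cortical
porosity, anatomical shape variation beyond a scaled circular arch, or
inter-patient positioning. Passing tests therefore demonstrate that the
pipeline machinery is correct and self-consistent — not that the networks
would reach the same accuracy on clinical data.

## Stage-3 numerical choices

* **Cut stations.** The protocol's "designated jaw area" is taken as the
  clinical premolar/molar regions flanking the foramen: each canal point
  is projected onto the bone line and the station is offset 6 px along the
  arc toward the midline. Cutting exactly through the foramen would scan
  a void, not intact cortex — the clinical measurement protocol likewise
  avoids the foramen itself. Stations and the offset are configurable.
* **Cross-section sampling.** Bilinear interpolation in-plane at 1 px
  steps along the cut normal (half-extent default 30 px ≈ 9 mm), nearest
  slice across the stack, fill value 0 outside the volume.
* **Binarization.** The scan needs a binary cortical mask; the choice of
  threshold is explicit: `fixed` (used for phantoms: the midpoint between
  the normalized trabecular and cortical intensities), `otsu`, or
  `multiotsu` (three-class split keeping the brightest class — the robust
  choice when trabecular bone is present in the cut). A grayscale scan
  mode (same argmax/argmin arithmetic on raw intensities) is kept behind a
  flag.
* **Boundary scan border case.** The scan rotates the mask 270 degrees and
  walks rows (= original columns, end-to-start), taking the first run of
  1s: first boundary by `argmax`, second by `argmin` after back-filling.
  When the run touches the end of a column there is no remaining 0 and a
  plain `argmin` would wrap to 0, reporting a negative thickness; the
  second boundary is then defined as the column length. Multi-run columns
  report the **first** run — a frozen consequence of the argmax/argmin
  semantics, pinned by a regression test.
* **Point estimate.** Per volume, the reported thickness is the median of
  all per-column thicknesses across the (default two) cuts.
* **Degenerate inputs.** Constant volumes normalize to all zeros; empty
  masks raise rather than reporting zero thickness; coincident bone-line
  points are rejected when fitting the polyline.

## Problem sizes and observed behaviour

The scaled-down experiment used throughout the tests and the acceptance
script: 200 noise-free phantoms (64x64 slices), split 70:30 (140/60),
small backbone; classifier 24 epochs (batch 16), regressor 60 epochs. At
these sizes the classifier reaches ~93-96% per-slice validation accuracy
and >=95% slice-hit rate, the regressor ~1 px validation L1 (0.3 mm), and
the end-to-end thickness error stays within 1 px (MSE well under 1 px²
over 50 phantoms spanning 2-8 px true thickness). The full 101-layer
backbone is validated structurally (stem surgery, feature width, simplex
output) but not trained in the test suite.

## Known limitations

* The numpy network engine is CPU-only and single-threaded beyond BLAS;
  it is sized for desk-scale experiments, not clinical volumes.
* No pretrained backbone weights ship with the package; the
  `pretrained_backbone` flag requires a caller-supplied weights file.
* Normalization is per-volume (a per-slice option is noted in the config
  but per-volume is the contract); slices of extreme dynamic range within
  one volume shift each other's scale.
* The boundary scan measures the first cortical run along each cut; if
  binarization leaks trabecular bone into the mask the first run can merge
  with it, which is why the fixed/multiotsu thresholds matter.
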