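# mandicort

Mandibular cortical bone thickness estimation from CBCT volumes, as a
three-stage modular pipeline with a synthetic-phantom test bed.

Thinning of the cortical bone at the base of the mandible is a radiologic
marker of osteoporotic change, and cone-beam CT (CBCT) — routinely
acquired for dental implant planning — resolves it well. `mandicort`
implements the automated measurement chain:

1. **Stage 1 — slice selection.** A residual classification network (first
   convolution re-fitted for single-channel input: 1→64 channels, 7×7,
   stride 2, padding 3, no bias; head `Linear(f, 512) → ReLU → Dropout(0.2)
   → Linear(512, 2) → softmax`) assigns every axial slice a probability of
   being the *correct* slice, the one showing both mental foramina. The
   highest-probability slice is selected. Training: SGD, lr 0.001,
   cross-entropy.
2. **Stage 2 — landmark regression.** The same backbone with a
   `Linear(512, 14)` head predicts 7 landmarks — 5 bone-line points and 2
   canal points — as raw pixel coordinates (x₁, y₁, …, x₇, y₇). Training:
   Adam, lr 0.001, L1 (mean absolute coordinate error, px).
3. **Stage 3 — thickness.** The bone-line points define a polyline;
   orthogonal cross-sections are cut near the canal projections, binarized,
   and scanned column-by-column: first boundary `ind1 = argmax(column)`,
   second boundary `ind2` = first zero after back-filling the run. The
   difference is the cortical thickness in px; mm = px × 0.3 (isotropic
   0.3 mm voxels).

Patient CBCT data of this kind are not publicly available, so the package
ships a first-class phantom generator: horseshoe-shaped cortical shells of
known thickness around a trabecular band, with two canal voids present
only on a narrow band of "valid" slices, plus noise — giving exact ground
truth for every stage. Two backbone depths are provided: the full
101-layer bottleneck network, and a small residual variant sized for CPU
experiments (see `docs/methods.md`).

The networks run on a small, fully-tested numpy engine (convolution,
batch norm, residual blocks, SGD/Adam, manual backprop) — no GPU or deep
learning framework required.

## Worked example

Train both stages on 200 noise-free phantoms (70:30 split) and evaluate
everything:

```sh
mandicort experiment --n 200 --seed 7 --out report.json
```

which prints (abridged):

```json
{
  "n": 200,
  "split": {"train": 140, "val": 60},
  "stage1": {
    "val_accuracy": 0.98,
    "val_precision": 0.90625,
    "val_recall": 0.96667,
    "val_slice_hit_accuracy": 1.0
  },
  "stage2": {"val_mae_px": 0.39678},
  "stage3": {"mse": 0.26639, "mean_error": 0.23068, "truth_mean": 3.98599,
             "truth_sd": 1.15917, "n": 60}
}
```

Reading: the slice classifier labels 98% of held-out slices correctly and
its argmax slice lands inside the labelled valid band on every held-out
volume; the landmark regressor's per-coordinate error is 0.40 px (≈ 0.12
mm at 0.3 mm/px); and the full pipeline — selected slice, predicted
landmarks, boundary scan — recovers the true cortical thickness with a
mean squared error of 0.27 px² over the 60 validation phantoms (true
thicknesses 2–6 px, mean 3.99 px).

Per-volume use, given trained weights:

```sh
mandicort phantom generate --n 1 --seed 3 --out data/
mandicort run --volume data/phantom_0000.nrrd --config cfg.yaml --out report.json
```

The report contains the selected slice and its probability, the 7
landmarks, the cut stations, and per-cut thickness profiles in px and mm.

The same operations are available as a library:

```python
from mandicort import (PhantomSpec, generate_phantom, normalize_volume,
                       PipelineConfig, run_pipeline)
```

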