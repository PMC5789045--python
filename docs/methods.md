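# Methods

## Model and assumptions

The grading model treats a localised knee-joint radiograph as two
anatomically fixed attention zones — the lateral and medial joint margins —
and classifies the joint from those zones only. The core assumption is
*feature-level* symmetry: edge/osteophyte/sclerosis detectors useful on the
lateral margin are equally useful on the mirrored medial margin, so one set
of convolutional and batch-normalisation weights serves both patches. The
joint itself is not assumed symmetric; only the learned features are. This
constraint halves the branch parameter count and acts as a strong prior
against attending to background structures.

Each branch stacks exactly five valid (unpadded) 3 × 3 convolutions so that
every layer strictly shrinks the map and first-layer detail is preserved:
stride 2 in the first convolution, 2 × 2 max-pools after convolutions 2 and
3, Conv → BN → ReLU ordering, global average pooling at the end. For a
128-px patch the pre-GAP map is 10 × 10, which fixes the native resolution
of the attention maps. The head is concatenation → dropout → linear → 5
logits; grade probabilities come from a softmax.

Ensembling imitates a reader committee: M = 3 models differ only in the
training seed (21, 42, 84), and their pre-softmax score vectors are summed
before one softmax. Summing upstream of the softmax sharpens the fused
distribution where members agree (a temperature effect); the alternative —
averaging member softmax outputs — is flatter but was not adopted.

Attention maps are gradient-weighted class activation maps taken at the
pre-GAP layer: the weight of channel k in branch i for class c is the
gradient of the class score with respect to that branch's pooled feature k.
Because global average pooling sits directly between that layer and the
head, this pooled-feature gradient equals the spatial average of the
per-pixel gradients — the classic two-step formulation — up to the positive
factor 1/(XY), which min–max normalisation absorbs. For the same reason,
guided backpropagation would be a no-op here: no rectification lies between
the chosen layer and the score, so its gradient rule never fires. Plain
backpropagation is therefore used, and the test suite checks the
pooled-gradient route against the explicit spatial-average formulation on
random networks. For an ensemble, the class score is the fused (summed)
score; by linearity the ensemble map is the entrywise sum of member maps,
branch by branch.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| crop size | 130 | mm | fixed physical field of view across devices |
| resized grid | 300 | px | working resolution after the crop |
| patch side S | 128 | px | covers one joint margin at the working grid |
| vertical offset K | 100 | px | places the joint line mid-patch |
| base width N | 64 | channels | widths [N/2, N/2, N, N, N]; 2N-dim descriptor |
| dropout | 0.2 | — | after concatenation only |
| lr / weight decay | 1e-2 / 1e-4 | — | Adam, cross-entropy |
| batch | 64 | pairs | full-scale recipe |
| iterations / eval | 50 000 / 500 | — | snapshot per evaluation |
| percentiles | 5th / 99th | — | tail truncation before 8-bit mapping |
| exposure band | [60, 180] | 8-bit mean | test-time gamma trigger |
| gamma grid | 0.5, 0.67, 1.5, 2.0 | — | first gamma that lands the mean in band |

Patch placement: the lateral patch starts at x = 0 and the medial patch is
right-aligned at x = resized − S (= 172), both with top edge at y = K. An
alternative "literal" reading that puts the medial origin at x = S − K
(= 28) is constructible through `PatchGeometry.default(medial="literal")`,
but it overlaps the lateral half and leaves the medial third of the joint
unobserved, so it is not the default — with it, lateral/medial branch
semantics and the attention back-projection lose their meaning.

## Synthetic phantoms

The generator renders what the model is designed to detect and nothing
more: a femoral and a tibial band on a soft-tissue background, separated by
a gap whose width falls with grade (6, 5, 4, 2.5, 1 mm, jittered ± 0.5 mm);
exponential marginal bumps (osteophytes) with grade-increasing amplitude;
3-mm subchondral bands brightened by a grade-increasing gain; Gaussian
noise, a global intensity offset, a small joint-line tilt and a random
left/right side. Per-grade gap means were chosen so a hand-crafted gap
measurement orders noise-free phantoms perfectly while adjacent grades
overlap under default noise — so learning is required but a desk-scale
CPU run succeeds in minutes. Each phantom carries a joint-margin mask
(± 4 mm around the bone edges, outer 40 mm of each side) used to test that
attention concentrates on the margins.

Phantoms deliberately lack trabecular texture, patellar and soft-tissue
shadows, implants, positioning variation and detector artefacts. Passing
tests on phantoms therefore demonstrates that the pipeline's mechanics —
geometry, optimisation, fusion, attention back-projection — recover a known
generative grade signal; they say nothing about accuracy on clinical
radiographs, which requires the restricted cohorts and full-scale training.

## Numerical choices

- **8-bit rounding**: round-half-to-even (`np.rint`) then clip to [0, 255],
  applied wherever an intensity returns to 8 bits.
- **Centre crop**: pixel count `round(target_mm / spacing)`; an odd margin
  leaves the extra pixel at the bottom/right, making crops deterministic.
- **Resampling**: bilinear for image resizing and for upsampling 10 × 10
  attention maps (endpoint-aligned); patches are cut by integer indexing
  after resizing — no subpixel cuts. Mask projection uses nearest-neighbour.
- **Fusion stability**: softmax with max subtraction; fused probabilities
  are validated to sum to 1 within 1e-6.
- **Overlay blending**: where the two patch projections overlap, the
  pointwise maximum is kept (sum would break the [0, 1] reading after
  min–max normalisation). An identically zero raw map yields an all-zero
  overlay rather than 0/0.
- **Batch norm**: biased batch variance in training, running statistics
  (momentum 0.1) at evaluation; evaluation-mode forward passes are bitwise
  deterministic. With lr = 0 the learnable weights are provably frozen, but
  running statistics still track the sampled batches.
- **Max pooling**: odd trailing rows/columns are dropped (floor semantics),
  matching the published spatial trace.
- **Degenerate inputs**: constant images raise a degenerate-input error at
  truncation; kappa is refused when both raters use a single identical
  grade; ROC requires both OA and non-OA cases; architecture validation
  reports the first layer whose map collapses.
- **Standardisation**: patches are standardised per sample (zero mean, unit
  variance per patch) at tensor conversion; the 8-bit stage performs no
  per-image zero-mean step.
- **Snapshot selection**: highest validation quadratic kappa, earliest
  iteration on ties; validation loss is logged but never used for selection.
- **Engine**: the network runs on a NumPy engine written for this package
  (im2col convolutions as single GEMMs, explicit backward passes, Adam with
  classic L2 coupling). Backward passes are verified against
  finite differences layer-by-layer and end-to-end in the test suite;
  gradient accumulation (`+=`) is what lets one layer object serve both
  branches per step.

## Open design choices taken

- "Average multi-class accuracy" is reported as mean per-class recall
  (balanced accuracy); plain accuracy is emitted alongside since either
  reading is defensible.
- Classification MSE is computed on argmax (hard) grades.
- The binary OA screening score is the tail mass p2 + p3 + p4.
- The test-time exposure rule (unspecified upstream of this implementation)
  is: correct only if the mean leaves [60, 180], trying the gamma grid in
  order and keeping the first in-band result, else the closest.
- Augmentation magnitudes: rotation ± 10°, brightness ± 30 (8-bit),
  contrast × [0.8, 1.2], jitter ± 15 px, gamma [0.8, 1.25], applied in
  random order, followed by the 130-mm crop.
- Desk-scale study conditions used by the end-to-end tests: 500 phantoms
  (100 per grade, 60/20/20 split), base width 8, batch 32, 200 iterations
  evaluated every 50, seeds 21/42/84, no augmentation (phantoms already
  randomise pose and intensity; the static pipeline lets patch pairs be
  precomputed once). These sizes were fixed once, before measuring, as the
  smallest configuration a CPU practitioner would call a real training run.

## Known limitations

- The full-scale cohort metrics of the clinical problem are out of scope:
  no access to graded radiograph cohorts, no GPU-scale training.
- Knee-joint localisation in full radiographs is consumed as input
  (bounding boxes), not performed.
- The NumPy engine is single-threaded-deterministic and CPU-oriented; it is
  not a general deep-learning framework (no padding, fixed 3 × 3 kernels,
  no learning-rate schedules).
- DICOM reading extracts pixels and ImagerPixelSpacing only; modality LUTs,
  photometric inversions and implant exclusion are the caller's
  responsibility.
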