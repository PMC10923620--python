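# Methods

## Problem and approach

Hepatocellular carcinoma (HCC) appears hypointense against enhancing liver
parenchyma in the hepatobiliary phase (HBP) of Gd-EOB-DTPA-enhanced MRI,
with complementary contrast in the portal venous phase (PVP). `hccseg`
implements a semiautomatic dual-phase segmentation method around three
models:

* **DCNN-F** — a single-phase encoder-decoder network applied to full-size
  HBP slices;
* **DFN-F** — a deep fusion network: two phase-specific sub-networks whose
  score maps are combined elementwise and mapped through a trainable fusion
  block, applied to full-size dual-phase slices;
* **DFN-R** — the same fusion network trained and applied only inside a
  radiologist-supplied 3D region of interest, with predictions pasted back
  into the full grid.

The qualitative claim behind the design is DCNN-F ≤ DFN-F ≤ DFN-R in mean
Dice: a single phase cannot distinguish tumor from dark-in-HBP confounders,
fusion can reject them using PVP intensity, and the ROI excludes them
outright. The test suite asserts this at two levels: mechanism tests verify
each ingredient in isolation (the phase-1 model is fooled by the mimic, the
phase-2 model vetoes it while retaining lesion recall, the ROI paste
excludes it geometrically), and an end-to-end property test asserts the
full mean-DSC ordering across seeds of the smallest cross-validated
comparison. At that smallest scale the full-chain ordering is *not* a
reliable outcome — see "What the phantom experiments can and cannot show"
below.

## Network architecture

The single-phase network is U-Net-like. The contracting path is six
3×3-conv + batch-norm + ReLU blocks with a 2×2/stride-2 max pool after
every second block (three pools), then two 1×1 conv blocks at the
bottleneck. The expansive path is three up-blocks (2×2 stride-2 transposed
convolution, concatenation with the matching encoder feature map, two 3×3
conv blocks), then a 1×1 conv and a sigmoid producing a per-pixel tumor
probability. Channel widths start at `base_channels` (default 32; 8 or 4 in
the desk presets) and double after every pool. Input height/width must be
divisible by 8.

The fusion network runs one such sub-network per phase, sums the two
sigmoid score maps elementwise, and maps the sum through a fusion block of
two 3×3 conv-BN-ReLU layers, a 1×1 conv, and a sigmoid. The exact depth and
width of the fusion block is a design choice of this package (the combining
rule — an elementwise sum feeding a learned mapping — is the method's
defining structure); a channel-concatenation variant is available via
`fusion_mode="concat"` for ablation.

Losses: soft Dice `1 − (2Σpg + s)/(Σp + Σg + s)` per network (smoothing
`s = 1` by default, `s = 0` allowed for exact analytics), and for the fusion
network the composite `Σᵢ αᵢ·L_subnetᵢ + L_fusion` with `α = (0.5, 0.5)`.

The whole engine — convolutions via im2col, transposed convolutions,
batch normalization, pooling, bilinear upsampling, Adam and SGD — is
implemented in NumPy with hand-derived backpropagation, verified against
finite differences in the test suite. It is exact, deterministic, and CPU-
sized; it is not intended for clinical-scale throughput.

## Training protocol

Single-phase training has three stages, all seeded and deterministic:

1. **Encoder pre-training** on non-augmented tumor slices. The contracting
   path alone cannot emit a mask, so a temporary auxiliary head (1×1 conv +
   fixed bilinear ×8 upsample + sigmoid) is attached at the bottleneck,
   trained with Dice loss, and discarded; only encoder weights are kept.
   This head is this package's mechanism choice for "train the feature
   extraction pathway first".
2. **Full-network training** on the same non-augmented slices.
3. **Fine-tuning on augmented data** (rotation −20°…20°, scale 0.9–1.1,
   contrast shift −5…5 on a 0–255 scale, additive Gaussian noise, horizontal
   mirroring). Geometric draws are shared between phases and mask;
   photometric draws are independent per phase and never touch the mask.

Fusion training splits the training cases (never slices) into two
near-equal subsets: subset A staged-trains the two sub-networks (phase 1
and phase 2 respectively); subset B then trains the fusion block with SGD
under the composite loss. Three small-data refinements, each chosen for a
measured mechanism rather than an outcome:

* sub-networks receive the same *gradient-step* budget a full-set model
  would get ("same training strategy" read as same optimization budget):
  subset A holds roughly half the slices, so its per-stage epochs are
  scaled up by the data ratio;
* with frozen sub-networks their score maps are constants, so they are
  computed once in eval mode and the (tiny) fusion block is trained to
  convergence on the cached maps, with a step learning-rate decay at 2/3
  of the epochs; subset B is augmented the same way as stage 3;
* the fusion block is initialized as a calibrated pass-through — identity
  -on-sum conv blocks plus a head set to a logistic fit of tumor
  probability against the summed score map on subset B — so gradient
  descent refines a sensible pixelwise operating point instead of random
  noise.

Batch-norm statistics are recalibrated exactly (one full pass, exact
moments) after every training phase: with only dozens of momentum updates
the running estimates otherwise lag the trained feature distribution, and
the train/eval normalization mismatch dominated generalization error in
bring-up experiments.

Evaluation is leave-one-case-out cross-validation with volume-level
confusion counting: one DSC/precision/recall triple per held-out case,
never per-slice averaging. Fold manifests record the training-case ids so
the no-leakage property is auditable.

## Learning rates and scale

The reference protocol is Adam at 1e-4 for the single network and SGD at
1e-7 for fusion fine-tuning, batch size 8; these are the `TrainConfig`
defaults. The phantom experiments run at a vastly smaller scale (hundreds
of gradient steps rather than tens of thousands), where those rates
perform essentially no optimization, so the presets use Adam 3e-3, SGD
2e-2 with momentum 0.9, and freeze the sub-networks during fusion
fine-tuning. Freezing is the desk-scale analogue of the reference
protocol's 1e-7 fusion rate, which leaves sub-network weights effectively
unchanged; at these step counts an unfrozen SGD rate large enough to train
the fusion block destroys the sub-networks instead (an optional
`dfn_subnet_lr` enables gentle unfrozen fine-tuning). Presets use
augmentation multiplicity 4 — the reference protocol's own small-data
remedy, which augments ~62x — with stage-3 epochs scaled down to keep step
counts bounded; at multiplicity 1 the sub-networks, which see only half
the cases, overfit lesion positions. All budgets are configurable.

## Preprocessing and registration

Phase 2 is registered to the phase-1 grid with a multiresolution B-spline
free-form deformation (SimpleITK): mean-squared intensity metric evaluated
on the full grid (no random sampling, hence deterministic), LBFGSB
optimizer, control-point spacing 16 voxels at the finest level, 3 pyramid
levels by default. Slices are selected where the mask has foreground,
min-max normalized per slice (a constant slice maps to zeros), and
resampled bilinearly (masks: nearest-neighbor) to the network grid.
Registration quality is scored inside the liver mask: displacement of
empty background is unobservable from intensities and the B-spline
regularity legitimately leaves it near zero there. Divergence is judged on
the finest pyramid level's metric trace, since metric values are not
comparable across levels.

## ROI geometry

A radiologist's intervention is three rectangles on the x-y, x-z, and y-z
planes. Each axis of the 3D box takes the union of the two rectangle ranges
constraining it, plus a margin (default 2 voxels), clipped to the volume;
union rather than intersection because missing tumor is the costly error in
this workflow. All coordinates are 0-based, half-open, on the phase-1 grid.
In the experiments (no human in the loop) boxes are the ground-truth
bounding box with ±2-voxel face jitter plus margin. ROI inference resamples
each cropped slice to a fixed network input size (24×24 in the presets),
and resamples score maps back bilinearly *before* thresholding to avoid
blocky masks. With a full-volume box, ROI-constrained inference is
bit-identical to full-size inference — an asserted reduction property.

## Synthetic phantoms

Each case is a pair of co-registered-in-truth volumes in [0, 1]:

* an ellipsoidal liver (intensity 0.60, mild smooth texture ±0.02) on a
  0.08 background; the liver spans the full z extent of the volume, as an
  abdominal FOV does, so every axial slice contains tissue;
* 1 or more lobulated lesions (ellipsoids modulated by low-frequency radial
  noise) with intensity offset −0.35 in phase 1 and −0.10 in phase 2
  (free parameters: no public quantitative contrast calibration for
  Gd-EOB-DTPA exists in this artifact's inputs);
* confounders: `organ_mimic` inserts a structure with lesion-like phase-1
  intensity but normal-liver phase-2 intensity (indistinguishable from
  tumor in phase 1 by construction); `unclear_boundary` blurs the lesion
  rim (σ = 2 voxels), reducing the border gradient by more than 40%;
* a smooth inter-phase misalignment: three Gaussian displacement bumps
  (σ ≥ 8 voxels, amplitude capped below σ/2, so smooth and invertible in
  practice), default maximum amplitude 2 voxels. Phase 2 is rendered
  through the numerically inverted field (fixed-point iteration), so the
  stored `true_deformation` is exactly the field a fixed-grid registration
  should recover;
* additive Gaussian noise, σ = 0.02 of the dynamic range, independent per
  phase. Rician noise is a documented extension, not implemented.

What the phantoms do **not** emulate: MR physics (relaxometry, k-space,
bias fields), anatomy beyond one organ, inter-patient intensity variation,
breathing-induced sliding motion, or partial-volume effects. Passing tests
therefore demonstrate that the pipeline's machinery behaves as specified
and that the method's failure-and-rescue mechanisms operate under its
assumed contrast structure — not that the reported clinical accuracy would
be reproduced on real MRI.

## Problem sizes

The packaged experiment presets are deliberately small so a full
three-model cross-validated comparison runs in minutes on one CPU:
`smoke_preset` uses 4 cases of 32×32×8 voxels, base width 4 (~90 s per
master seed for all three models under leave-one-out CV); `desk_preset`
uses 8 cases of 64×64×16, base width 8. The cohort-scale configuration
(51 cases, 256×256 slices, base width 32, multiplicity ≈ 62 giving
~26,000 augmented pairs from 417) is expressible with the same
configuration objects but is not exercised by the test suite.

## What the phantom experiments can and cannot show

The ingredient mechanisms are robustly demonstrable at the smallest scale
and are asserted by the mechanism tests. The *full-chain* mean-DSC
ordering DCNN-F ≤ DFN-F ≤ DFN-R is a different matter. With 4 cases per
cohort, per-seed model means carry a standard deviation around 0.15–0.2,
while the fusion advantage being tested is of order 0.05; moreover the
mandatory two-subset protocol halves the sub-networks' training data (2
of 3 training cases go to subset A), a cost that at this cohort size is
comparable to the confounder penalty it is meant to overcome. In measured
5-seed runs the ROI-constrained model leads the single-phase baseline in
most seeds, but the middle link (DFN-F above DCNN-F) does not resolve
above noise, so the end-to-end ordering property fails at this scale.
Scaling the cohort to the point where the ordering stabilizes (tens of
cases, as in the original setting) is beyond what the pure-NumPy training
engine can do in an interactive test run; the end-to-end ordering test is
retained at the smallest scale as an honest record of this limit rather
than weakened to pass.

## Numerical conventions

* Empty-vs-empty masks score DSC = precision = recall = 1; a ratio whose
  denominator alone is zero is 0.
* Aggregates use the sample (n−1) standard deviation; std of a single case
  is 0 by convention.
* The paired t-test is two-sided, p from the regularized incomplete beta;
  an all-zero difference vector is flagged degenerate with (t = 0, p = 1).
* Score-map binarization uses `>=` at threshold 0.5.
* Batch norm uses momentum 0.1 and eps 1e-5; eval mode uses running stats.
* Determinism: every stochastic component (phantom generation, subset
  splits, shuffling, initialization, augmentation draws) derives from
  explicit integer seeds; registration runs single-threaded with full
  metric sampling. Two runs of one experiment configuration produce
  byte-identical metric files on the same platform.

## Known limitations

* The NumPy engine is single-threaded-BLAS bound; cohort-scale training is
  out of reach by design.
* The phantom's confounders are stylized; the organ mimic lives inside the
  liver volume rather than in an adjacent organ.
* ROI boxes in the experiments derive from ground truth (jittered), not
  from human input; inter-rater ROI variability is not modelled.
* Registration recovers only the component of the deformation visible in
  intensity structure; residuals are reported inside the liver.
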