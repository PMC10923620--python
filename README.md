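# hccseg

Semiautomatic segmentation of hepatocellular carcinoma (HCC) in dual-phase
Gd-EOB-DTPA-enhanced liver MRI.

HCC is hypointense against the enhancing parenchyma in the hepatobiliary
phase (HBP) and shows complementary contrast in the portal venous phase
(PVP). A single phase is often not enough: vessels and adjacent organs can
be as dark as tumor in HBP, and cirrhotic livers can blur the tumor border.
This package implements a segmentation method built around that problem and
a synthetic-phantom harness that reproduces its failure modes, for
researchers studying multi-phase fusion and human-in-the-loop segmentation.

## The method

Three models of increasing intervention:

* **DCNN-F** — an encoder-decoder network (U-Net-like: six 3×3 conv-BN-ReLU
  blocks with three 2×2 max pools, two 1×1 bottleneck convs, three
  deconv/skip up-blocks, sigmoid head) trained on full-size HBP slices with
  soft Dice loss, `L(p,g) = 1 − (2Σpg + s)/(Σp + Σg + s)`.
* **DFN-F** — a deep fusion network. Each phase `P_i` feeds its own
  sub-network with weights `W_i`; the final map is
  `H(P, W) = f(Σᵢ o(Pᵢ, Wᵢ))`, where `f` is a trainable fusion block.
  Training minimizes the composite loss
  `L(G, P; α) = Σᵢ αᵢ·L_subnetᵢ(G, Pᵢ) + L_DFN(G, P_out)` with
  `α = (0.5, 0.5)`: sub-networks are staged-trained on one half of the
  training cases, the fusion on the other half.
* **DFN-R** — the same fusion network constrained by a radiologist's ROI:
  three dragged rectangles on the x-y, x-z, and y-z planes define a 3D box
  (per-axis union + margin); the network trains and predicts on crops only,
  and predictions are pasted back into the full grid, zero outside the box.

Evaluation is leave-one-case-out cross-validation with volume-level
`DSC = 2TP/(FP + 2TP + FN)`, precision, and recall per case, and two-sided
paired t-tests between models. Since no public dual-phase HCC cohort
exists, the package ships a phantom generator whose cases carry the exact
contrast structure the method assumes — including an `organ_mimic`
confounder that phase 1 cannot distinguish from tumor but phase 2 can, and
known smooth inter-phase misalignment corrected by B-spline registration.
The networks and their training are implemented as a self-contained,
fully deterministic NumPy engine with hand-derived backpropagation (see
`docs/methods.md`).

## Worked example

Run the smallest end-to-end comparison (4 phantom cases with organ-mimic
confounders, 32×32×8 voxels, three models under leave-one-out CV; about
90 seconds on one CPU):

```bash
hccseg experiment --preset smoke --seed 0 --out results/smoke
```

which prints the comparison table (this exact output for seed 0):

```
Model                                  DSC                        PRECISION                           RECALL       p
DCNN-F       0.58±0.22 med 0.62 [0.29-0.78]   0.46±0.18 med 0.47 [0.24-0.64]   0.82±0.30 med 0.95 [0.36-1.00]        —
DFN-F        0.54±0.05 med 0.52 [0.51-0.60]   0.44±0.07 med 0.44 [0.36-0.53]   0.75±0.21 med 0.76 [0.50-0.97]    0.690
DFN-R        0.69±0.20 med 0.66 [0.48-0.95]   0.73±0.32 med 0.79 [0.35-1.00]   0.76±0.23 med 0.84 [0.43-0.93]    0.344
```

Reading it: the single-phase model (DCNN-F) recalls most tumor voxels
(recall 0.82, median 0.95) but its precision is poor (0.46) — the phantom's
organ mimic is exactly as dark as tumor in phase 1 and the model marks it
wholesale. Constraining the fusion network to the radiologist-style ROI
(DFN-R) excludes the confounder outright and gives the best mean DSC (0.69)
and precision (0.73). At this 4-case scale the full-size fusion model
(DFN-F) does not separate from the single-phase baseline: halving the
training cases between its sub-networks and its fusion block costs about as
much as the dual-phase veto gains (see `docs/methods.md`, "What the phantom
experiments can and cannot show"). The `p` column is the paired t-test of
each model's per-case DSC against the first row. `results/smoke/` holds
`metrics.json` (per-case values), `report.csv`/`report.txt`, and
`folds.json` (training-case audit per fold).

The same models are available as scikit-learn-style estimators:

```python
from hccseg.estimators import FusionSegmenter
est = FusionSegmenter(base_channels=8, random_state=0)
est.fit(X, y, groups=case_ids)      # X: (n, 2, H, W), y: (n, H, W)
masks = est.predict(X)              # (n, H, W) binary
```

Other CLI subcommands: `simulate` (write a phantom cohort as NIfTI +
manifest), `preprocess` (B-spline registration of phase 2 onto phase 1),
`segment` (one case, optionally with `--roi roi.json` for DFN-R mode), and
`evaluate` (score prediction masks).

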