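# Methods

## The camouflage-degree metric

An object is treated as camouflaged when its colour distribution is close to
the background's. Per object we build per-channel RGB histograms of the
foreground and background regions, normalise counts to probabilities, and sum
the per-channel chi-square distances

    Tgc = Σ_{c∈{R,G,B}} Σ_i (h1(i) − h2(i))² / (h1(i) + h2(i)),

skipping bins where both probabilities vanish (0/0 contributes 0). Because
each channel's distance is bounded by 2, Tgc ∈ [0, 6]; it is symmetric,
vanishes iff the histograms agree, and is invariant under a common
permutation of bins. The dataset-level Camouflage Degree is the count ratio
CD = #{Tgc < 0.9} / #{Tgc ≥ 0.9}; the 0.9 threshold applies to the 3-channel
sum.

Choices the metric's definition leaves open, and our defaults:

- **Bin count** — 32 equal-width bins per channel over [0, 256), half-open
  intervals with the last bin closed at 255. Object boxes in pest imagery are
  frequently under a thousand pixels; 256 bins makes small-box histograms so
  sparse that the distance saturates, while 32 remains stable. Configurable
  via `CDConfig.n_bins`.
- **Region definition** — foreground is the axis-aligned box interior
  (rasterised floor(x,y) / round(w,h)); background is the whole image minus
  the union of *all* annotated boxes, which matches the dataset-level framing
  of the metric. A `local_surround` mode (3× dilated box minus the box union)
  is provided for images whose global background is heterogeneous. Both modes
  sit behind `CDConfig.background_mode` because the metric's source leaves
  the region definition open.
- Crowd annotations are excluded; grayscale images are replicated to three
  channels with a warning; objects with an empty background region are
  skipped with a warning and excluded from the counts.

## Synthetic scenes

The generator emulates the one property the metric and the detector care
about: controllable chromatic similarity between object and background.
Backgrounds are per-pixel samples from a 3-component Gaussian RGB mixture
(greenish vegetation tones); objects are ellipses or radially perturbed
blob polygons (12 control points, mimicking irregular insect outlines)
filled from an object palette (brown/tan body tones) whose component means
are linearly interpolated toward the background means by `alpha ∈ [0, 1]`.
Standard deviations are *not* blended: camouflage here is chromatic, so
texture variance survives. Per-pixel noise (σ = 4 by default, on top of
component σ = 12) keeps histograms spread across bins.

At `alpha = 0` the palettes occupy disjoint RGB octants and objects score
Tgc well above 0.9; at `alpha = 1` the object's colour distribution equals
the background's and Tgc falls to sampling noise. Mean Tgc is monotone
decreasing in alpha — the generator's core contract, verified statistically
over ≥ 50 scenes per level — which lets a dataset's CD be dialled from
COCO-like (≈ 0.26) to locust-like (≈ 1.05). Objects are placed without
overlap by rejection sampling (100 attempts, then skip with a warning);
the tight bounding box of the rasterised mask becomes the annotation.

What the generator does **not** emulate: texture camouflage, lighting and
shadow, perspective, occlusion by vegetation, class imbalance, or any
photorealism. Tests passing on these scenes show the pipeline's mechanics
are correct under controlled chromatic camouflage; they say nothing about
accuracy on real field imagery.

## Copy-paste augmentation

An annotated object (instance mask when available, else its box rectangle)
is rotated within ±30°, scaled within [0.7, 1.3], and pasted hard
(mask-replace; optional alpha blend) at a uniformly drawn position that fits
the image, with 50 placement retries before skipping. The transform ranges
are this package's defaults — chosen to keep objects recognisable — since
the procedure's description leaves them open. Destination annotations are
never mutated; occlusion of existing objects by a pasted one is allowed and
the occluded annotation kept, mirroring natural occlusion. Dataset-level
augmentation retains all originals and adds pasted-on copies of randomly
chosen destination images until a target count is reached.

## Detector

The detector is a DETR-style set-prediction model assembled from the
components below. All tensor math runs on a purpose-built numpy reverse-mode
autodiff engine (`keyfg.nn`): the op set (matmul, elementwise, softmax,
reductions, gather, padding, bilinear sampling differentiable in both
features and coordinates) is exactly what these components need, and every
op is verified against central finite differences.

- **Backbone.** The reference stage contract is ResNet-50 ("same" stride
  arithmetic: 1333×800 → 667×400×64 → … → 42×25×2048), exposed as a pure
  shape function. Training uses a four-stage stand-in with identical stride
  arithmetic but small channel counts, so no pretrained weights are needed
  and a forward pass stays in milliseconds. Its convolutions use edge
  padding, which preserves constant inputs — the property the heatmap
  diagnostics rely on.
- **Deformable attention.** Per head, K points per level are sampled at
  `p̂·(W_l, H_l) − 0.5 + Δp` by bilinear interpolation (outside samples
  contribute zero), combined with softmax-normalised weights over the L·K
  slots of each head, value-projected per head and output-projected.
  Offsets and weights are linear in the query; offset nets start at zero
  with sampling points spread on a unit circle. The batched layer is tested
  against an independent dense loop that re-implements the sum explicitly.
- **FGSP.** Class and foreground heads score every encoder token;
  `P_j = C_j · S_j` ranks tokens, the top `ceil(keep_ratio · N)` (ties to
  the lower index) are kept as query candidates, and the top `n_queries` of
  those initialise object queries: content from a linear map of the token,
  reference box from an auxiliary encoder box head around the token centre
  (base size 0.2 doubled per level). With FGSP disabled the ranking falls
  back to class scores alone and no filtering occurs, which together with
  DropKey ratio 0, no denoising and match-only loss weights reduces the
  model to a plain deformable-DETR-style pass (the ablation baseline).
- **MaskMLP.** Spatial branch: per-location MLP over the channel vector to
  one logit. Channel branch: spatially pooled vector through an MLP to C
  logits. Fused as `sigmoid(W_s ⊗ W_c)` — strictly inside (0,1), so masked
  features never exceed the originals in magnitude. Default insertion is on
  the projected encoder memory levels before decoder cross-attention; a
  `backbone` placement is available behind a config switch because the
  architecture description is ambiguous on the insertion point. Supervision:
  binary cross-entropy against ground-truth instance-mask unions pooled to
  each level grid, available for synthetic data; without masks the component
  is simply absent from the loss.
- **Denoising branch.** G groups (default 3 in the desk profile) of noised
  ground-truth copies: centres jittered within ±0.4·(w,h)/2, sizes scaled
  by U[0.6, 1.4], labels flipped to a random other class with probability
  0.2. The decoder self-attention mask blocks matching→denoising and
  cross-group attention (denoising→matching stays open). Each noised query
  regresses its own ground truth, no matching involved.
- **DropKey.** In decoder self-attention only (cross-attention is
  deformable), each query-key logit is masked to −∞ with probability 0.1
  before the softmax, training only. A row losing all keys falls back to
  unmasked attention with a logged warning.
- **Loss.** `total = λ_mm·L_match + λ_dd·L_dn + λ_mM·L_mask + λ_ff·L_fg +
  λ_ee·L_enc`, all λ defaulting to 1 (no reference values exist). L_match is
  sigmoid focal classification (α 0.25, γ 2, normalised by ground-truth
  count) over all queries plus L1 and GIoU over Hungarian-matched pairs,
  deep-supervised across decoder layers; Hungarian costs use
  w_cls 2 / w_L1 5 / w_giou 2. L_enc applies the same form to the encoder's
  auxiliary predictions on kept tokens. L_fg is BCE of S_j against
  token-centre-in-box labels.

### Desk profile and numerical choices

Defaults target a single CPU core: 64×64 inputs, d = 32, 2 pyramid levels
(strides 8 and 16), 2 heads, 2 points, 2+2 encoder/decoder layers, 12
queries, FFN width 64 — a forward+backward pass ≈ 0.12 s, so the test
suite's 100-epoch, 5-image overfit run completes in under half a minute.
A full-scale configuration (L=4, M=8, K=4, 6+6 layers, 300 queries,
1333×800) is expressible through the same `ModelConfig` but is not exercised
by the tests. Box coordinates are normalised (cx, cy, w, h) inside the model
with logit-space refinement (`sigmoid(Δ + logit(ref))`, refs detached
between layers); L1 uses `sqrt(x² + 1e-12)` for a finite gradient at zero;
probabilities are clipped to [1e-7, 1−1e-7] inside cross-entropies;
class-head biases start at −2 so initial foreground probabilities are low.

## Training and evaluation

Adam with decoupled weight decay 0.0005, initial learning rate 0.001,
cosine annealing to 1e-6 at the final epoch, batch size 4 via gradient
accumulation — the reference recipe. One master seed fans out (via
`SeedSequence`) into independent streams for model init, data order, and
train-time noise (DropKey masks, denoising jitter), making runs
reproducible; a non-finite loss aborts with a diagnostic.

Evaluation is self-contained COCO-style AP: per class, predictions ranked by
score are greedily matched to ground truths at each IoU threshold
0.5:0.95:0.05, precision is made monotone and sampled at 101 recall points;
AP averages thresholds and classes. Recall/precision/F1 are computed at
IoU 0.5 with score threshold 0.5 — an operating point this package fixes,
since the reference metrics never state one. The AP implementation is kept
in-package so the metric itself is testable against hand-built fixtures
(exact precision/recall on a 3-box example).

The ablation harness trains the module-toggle ladder EXP_A (no modules,
the deformable-DETR baseline) through EXP_E (MaskMLP + denoising + DropKey
+ FGSP) with a shared seed and emits a CSV of metrics per stage. At desk
scale only the *direction* of the progression is checked (EXP_E not worse
than EXP_A beyond noise); desk-scale runs cannot and do not reproduce any
benchmark AP figures, which would require the external image corpora and
GPU-scale training.

## Known limitations

- The chi-square camouflage metric sees colour only; textural or shape
  camouflage is invisible to it.
- The stand-in backbone is not a ResNet and carries no pretrained prior;
  absolute detection quality at desk scale is meaningless beyond the
  overfit/ordering properties the tests assert.
- Hungarian matching delegates to scipy's assignment solver; the exhaustive
  enumeration used in tests is the independent reference.
- Single-image (batch-accumulated) processing keeps the autodiff graphs
  simple but makes large-scale training impractical; the package is a desk
  reference, not a production trainer.
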