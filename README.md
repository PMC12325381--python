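# keyfg

Camouflage-degree quantification and DETR-style detection components for
camouflaged pest imagery — locusts on vegetation being the motivating case,
where the insect's colour distribution nearly matches the background and
conventional detectors lose the object.

The package serves two audiences: researchers who want to *measure* how
camouflaged a detection dataset is before choosing a model, and developers who
want desk-scale, fully inspectable implementations of the transformer-detector
components that help on such data.

## What it computes

**Camouflage Degree (CD).** For each annotated object, normalised per-channel
RGB histograms are built for the foreground (bounding-box interior) and the
background (image minus all boxes, or a local surround). The chi-square
distance per channel

    Tgc = Σ_c Σ_i (h1(i) − h2(i))² / (h1(i) + h2(i))

summed over the three channels measures foreground–background dissimilarity
(0 ≤ Tgc ≤ 6; smaller = more camouflaged). At the dataset level,

    CD = #{objects with Tgc < 0.9} / #{objects with Tgc ≥ 0.9}

so CD ≈ 1 or above marks a camouflaged dataset, while ordinary detection data
sits far below (a COCO-like corpus scores ≈ 0.26).

**Detector components.** The `keyfg.model` package implements, on a small
numpy autodiff engine written for this purpose:

- the ResNet-50 stage-shape contract and a desk-scale stand-in backbone with
  identical stride arithmetic;
- multi-scale deformable attention
  `MSDeformAttn(z_q, p̂_q, {x^l}) = Σ_m W_m [Σ_l Σ_k A_mlqk · W'_m x^l(φ_l(p̂_q) + Δp_mlqk)]`
  with softmax-normalised weights per head;
- the Fine-Grained Score Predictor (FGSP): per-token `P_j = C_j · S_j`
  (class × foreground probability) for token filtering and query placement;
- the dual-branch MaskMLP producing soft masks `sigmoid(W_s ⊗ W_c)` in (0,1);
- denoising query groups with a leakage-blocking attention mask;
- DropKey attention (keys masked before the softmax during training);
- Hungarian matching and the five-component composite loss
  (match + denoising + mask + foreground + encoder terms, each weighted).

**Supporting tooling.** COCO JSON I/O with validation, 7:3 hold-out
splitting, copy-paste augmentation (rotate/scale/paste with updated
annotations), a synthetic camouflage-scene generator whose single `alpha`
parameter dials objects from conspicuous to fully colour-blended, a training
harness (Adam, lr 0.001, weight decay 0.0005, cosine annealing, batch 4),
COCO-style AP/recall/F1 evaluation, EXP_A→EXP_E module ablations and
backbone heatmap export.

## Worked example

```python
import numpy as np
from keyfg.synthetic import SceneSpec, generate_dataset
from keyfg.histogram import CDConfig, score_dataset
from keyfg.train import TrainConfig, train, evaluate, predict_dataset

# 100 scenes, half fully blended (alpha=1), half conspicuous (alpha=0)
spec = SceneSpec(height=80, width=80, n_objects=1, min_radius=9, max_radius=14)
ds = generate_dataset(100, spec, seed=7, alphas=[0.0, 1.0])
rep = score_dataset(ds, CDConfig())
print(f"CD = {rep.cd:.2f}  ({rep.n_below} camouflaged / {rep.n_above} conspicuous)")

# desk-scale training: overfit five camouflaged scenes
train_ds = generate_dataset(5, SceneSpec(height=64, width=64, n_objects=1,
                                         alpha=0.9, min_radius=8, max_radius=14), seed=7)
model, log = train(TrainConfig(epochs=100, seed=1), train_ds)
m = evaluate(predict_dataset(model, train_ds), train_ds)
print(f"loss {log[0]['total']:.2f} -> {log[-1]['total']:.2f}; AP50 = {m.ap50:.2f}")
```

prints

```
CD = 1.00  (50 camouflaged / 50 conspicuous)
loss 14.48 -> 2.61; AP50 = 1.00
```

The CD of 1.00 reflects the 50/50 alpha mix (a conspicuous object scores
Tgc ≈ 1.2 here, a blended one ≈ 0.06, either side of the 0.9 threshold), and
the desk-profile detector drives its composite loss from 14.5 to 2.6 while
learning to localise every object at IoU ≥ 0.5 (AP50 = 1.0 on the training
scenes — an overfit check, not a generalisation claim).

A command-line interface mirrors the library:
`keyfg cd-score`, `keyfg generate`, `keyfg augment`, `keyfg train`,
`keyfg eval`, `keyfg ablate`, `keyfg heatmap` (see `keyfg --help`).

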