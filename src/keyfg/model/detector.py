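"""The assembled key-fg detector.

A DETR-style set-prediction detector for camouflaged objects:

* a convolutional backbone feeding an L-level feature pyramid projected
  to a shared width;
* an encoder of multi-scale deformable self-attention layers;
* an FGSP head scoring every encoder token (class x foreground
  probability) that filters tokens and initialises object queries at the
  top-scoring locations;
* MaskMLP soft masks applied to the memory levels before decoder
  cross-attention (or to the backbone features, by configuration);
* a decoder whose self-attention uses DropKey and whose cross-attention
  is multi-scale deformable, with iterative box refinement;
* a denoising branch of noised ground-truth queries isolated by an
  attention mask, active during training.

Everything runs on the package's numpy autodiff tensors; the desk-scale
default configuration keeps a forward/backward pass in the tens of
milliseconds on one CPU core.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

import yaml

from ..nn import (
    MLP,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    concat,
    relu,
    sigmoid,
)
from .backbone import TinyBackbone
from .boxes import cxcywh_to_xyxy, inverse_sigmoid
from .deform_attn import MSDeformAttention
from .denoise import DenoisingBatch, build_denoising_queries
from .dropkey import SelfAttention
from .fgsp import FGSPHead, fgsp_scores, select_foreground_tokens
from .maskmlp import MaskMLP
from .matcher import MatchWeights, hungarian_match
from .losses import LossWeights

__all__ = ["ModelConfig", "KeyFgDetector", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture and training-branch configuration.

    The defaults are the desk profile: 2 pyramid levels, 2 heads,
    2 sampling points, 2+2 layers and 12 queries on 64x64 inputs, small
    enough to overfit a handful of synthetic scenes in minutes on a CPU.
    A full-scale profile would use L=4, M=8, K=4, 6+6 layers and 300
    queries on 1333x800 inputs.
    """

    d_model: int = 32
    n_levels: int = 2
    n_heads: int = 2
    n_points: int = 2
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    n_queries: int = 12
    ffn_dim: int = 64
    n_classes: int = 1
    image_size: int = 64
    keep_ratio: float = 0.3
    dropkey_ratio: float = 0.1
    dn_groups: int = 3
    dn_box_noise: float = 0.4
    dn_label_flip: float = 0.2
    use_maskmlp: bool = True
    use_dn: bool = True
    use_dropkey: bool = True
    use_fgsp: bool = True
    maskmlp_place: str = "encoder"  # or "backbone"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    match_weights: MatchWeights = field(default_factory=MatchWeights)

    def __post_init__(self) -> None:
        if self.maskmlp_place not in ("encoder", "backbone"):
            raise ValueError("maskmlp_place must be 'encoder' or 'backbone'")
        if isinstance(self.loss_weights, dict):
            self.loss_weights = LossWeights(**self.loss_weights)
        if isinstance(self.match_weights, dict):
            self.match_weights = MatchWeights(**self.match_weights)

    # YAML round-trip using the external-config key names
    def to_yaml(self, path: str | Path) -> None:
        lw = self.loss_weights
        doc = {
            "levels": self.n_levels, "heads": self.n_heads,
            "points": self.n_points,
            "layers": {"encoder": self.n_encoder_layers,
                       "decoder": self.n_decoder_layers},
            "queries": self.n_queries, "d_model": self.d_model,
            "ffn_dim": self.ffn_dim, "n_classes": self.n_classes,
            "image_size": self.image_size,
            "keep_ratio": self.keep_ratio,
            "dropkey_ratio": self.dropkey_ratio,
            "dn": {"groups": self.dn_groups, "box_noise": self.dn_box_noise,
                   "label_flip": self.dn_label_flip},
            "loss_weights": {"match": lw.lam_match, "dn": lw.lam_dn,
                             "mask": lw.lam_mask, "fg": lw.lam_fg,
                             "enc": lw.lam_enc},
            "modules": {"maskmlp": self.use_maskmlp, "dn": self.use_dn,
                        "dropkey": self.use_dropkey, "fgsp": self.use_fgsp,
                        "maskmlp_place": self.maskmlp_place},
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        doc = yaml.safe_load(Path(path).read_text())
        lw = doc.get("loss_weights", {})
        dn = doc.get("dn", {})
        mods = doc.get("modules", {})
        return cls(
            d_model=doc.get("d_model", 32),
            n_levels=doc.get("levels", 2),
            n_heads=doc.get("heads", 2),
            n_points=doc.get("points", 2),
            n_encoder_layers=doc.get("layers", {}).get("encoder", 2),
            n_decoder_layers=doc.get("layers", {}).get("decoder", 2),
            n_queries=doc.get("queries", 12),
            ffn_dim=doc.get("ffn_dim", 64),
            n_classes=doc.get("n_classes", 1),
            image_size=doc.get("image_size", 64),
            keep_ratio=doc.get("keep_ratio", 0.3),
            dropkey_ratio=doc.get("dropkey_ratio", 0.1),
            dn_groups=dn.get("groups", 3),
            dn_box_noise=dn.get("box_noise", 0.4),
            dn_label_flip=dn.get("label_flip", 0.2),
            use_maskmlp=mods.get("maskmlp", True),
            use_dn=mods.get("dn", True),
            use_dropkey=mods.get("dropkey", True),
            use_fgsp=mods.get("fgsp", True),
            maskmlp_place=mods.get("maskmlp_place", "encoder"),
            loss_weights=LossWeights(
                lam_match=lw.get("match", 1.0), lam_dn=lw.get("dn", 1.0),
                lam_mask=lw.get("mask", 1.0), lam_fg=lw.get("fg", 1.0),
                lam_enc=lw.get("enc", 1.0),
            ),
        )

    def config_hash(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def _sinusoidal_pos(centers: np.ndarray, d: int) -> np.ndarray:
    """2-D sinusoidal positional encoding of normalised (x, y) centres."""
    dq = d // 4
    freqs = 1.0 / (50.0 ** (np.arange(dq) / max(dq, 1)))
    out = []
    for axis in range(2):
        ang = centers[:, axis:axis + 1] * 2 * np.pi * freqs[None, :]
        out.extend([np.sin(ang), np.cos(ang)])
    enc = np.concatenate(out, axis=1)
    if enc.shape[1] < d:
        enc = np.concatenate([enc, np.zeros((enc.shape[0], d - enc.shape[1]))], axis=1)
    return enc


class _FFN(Module):
    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)
        self.norm = LayerNorm(d)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(x + self.fc2(relu(self.fc1(x))))


class _EncoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.attn = MSDeformAttention(cfg.d_model, cfg.n_heads, cfg.n_levels,
                                      cfg.n_points, rng)
        self.norm = LayerNorm(cfg.d_model)
        self.ffn = _FFN(cfg.d_model, cfg.ffn_dim, rng)

    def __call__(self, tokens: Tensor, centers: np.ndarray,
                 level_maps: list[Tensor]) -> Tensor:
        x = self.norm(tokens + self.attn(tokens, centers, level_maps))
        return self.ffn(x)


class _DecoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ratio = cfg.dropkey_ratio if cfg.use_dropkey else 0.0
        self.self_attn = SelfAttention(cfg.d_model, cfg.n_heads, rng, ratio)
        self.norm1 = LayerNorm(cfg.d_model)
        self.cross_attn = MSDeformAttention(cfg.d_model, cfg.n_heads,
                                            cfg.n_levels, cfg.n_points, rng)
        self.norm2 = LayerNorm(cfg.d_model)
        self.ffn = _FFN(cfg.d_model, cfg.ffn_dim, rng)
        self.class_head = Linear(cfg.d_model, cfg.n_classes, rng)
        self.class_head.bias.data[:] = -2.0
        self.box_head = MLP([cfg.d_model, cfg.d_model, 4], rng)
        self.box_head.layers[-1].weight.data[:] = 0.0

    def __call__(self, q: Tensor, ref_boxes: np.ndarray,
                 level_maps: list[Tensor], rng, training: bool,
                 attn_mask: np.ndarray | None):
        pos = Tensor(_sinusoidal_pos(ref_boxes[:, :2], q.shape[1]))
        x = self.norm1(q + self.self_attn(q + pos, rng=rng, training=training,
                                          attn_mask=attn_mask))
        x = self.norm2(x + self.cross_attn(x + pos, ref_boxes[:, :2], level_maps))
        x = self.ffn(x)
        logits = self.class_head(x)
        delta = self.box_head(x)
        boxes = sigmoid(delta + Tensor(inverse_sigmoid(ref_boxes)))
        return x, logits, boxes


class KeyFgDetector(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        cfg = config
        self.backbone = TinyBackbone(rng)
        chans = TinyBackbone.STAGE_CHANNELS[1:1 + cfg.n_levels]  # res3..res5
        self.input_proj = [Linear(c, cfg.d_model, rng) for c in chans]
        self.level_embed = Tensor(
            rng.normal(0, 0.02, size=(cfg.n_levels, cfg.d_model)),
            requires_grad=True,
        )
        self.encoder_layers = [_EncoderLayer(cfg, rng)
                               for _ in range(cfg.n_encoder_layers)]
        self.fgsp_head = FGSPHead(cfg.d_model, cfg.n_classes, rng)
        self.enc_box_head = MLP([cfg.d_model, cfg.d_model, 4], rng)
        self.enc_box_head.layers[-1].weight.data[:] = 0.0
        self.query_proj = Linear(cfg.d_model, cfg.d_model, rng)
        self.maskmlp = MaskMLP(cfg.d_model, cfg.d_model, rng) if cfg.use_maskmlp else None
        self.maskmlp_backbone = (
            [MaskMLP(c, cfg.d_model, rng) for c in chans]
            if cfg.use_maskmlp and cfg.maskmlp_place == "backbone" else None
        )
        self.label_embed = Tensor(
            rng.normal(0, 0.02, size=(cfg.n_classes + 1, cfg.d_model)),
            requires_grad=True,
        )
        self.decoder_layers = [_DecoderLayer(cfg, rng)
                               for _ in range(cfg.n_decoder_layers)]

    # ------------------------------------------------------------------
    def _token_geometry(self, shapes: list[tuple[int, int]]):
        centers = []
        level_id = []
        for l, (H, W) in enumerate(shapes):
            ys, xs = np.mgrid[0:H, 0:W]
            cx = (xs.ravel() + 0.5) / W
            cy = (ys.ravel() + 0.5) / H
            centers.append(np.stack([cx, cy], axis=1))
            level_id.append(np.full(H * W, l))
        return np.concatenate(centers), np.concatenate(level_id)

    def forward(self, image: np.ndarray, targets: dict | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        """Run the detector on one (H, W, 3) uint8/float image.

        Returns the output dictionary consumed by
        :func:`keyfg.model.losses.composite_loss` plus ready-to-use
        numpy predictions under ``pred_scores`` / ``pred_boxes_xyxy``.
        """
        cfg = self.config
        rng = rng or np.random.default_rng()
        img = np.asarray(image, dtype=float)
        if img.max() > 1.5:
            img = img / 255.0
        x = Tensor(img - 0.5)

        feats = self.backbone.feature_levels(x, cfg.n_levels)
        if self.maskmlp_backbone is not None:
            soft_masks_bb = [m(f) for m, f in zip(self.maskmlp_backbone, feats)]
            feats = [sm.apply(f) for sm, f in zip(soft_masks_bb, feats)]
        shapes = [f.shape[:2] for f in feats]
        centers, level_id = self._token_geometry(shapes)

        proj_maps = []
        token_parts = []
        for l, f in enumerate(feats):
            H, W = f.shape[:2]
            p = self.input_proj[l](f.reshape(H * W, f.shape[2]))
            token_parts.append(p + self.level_embed[l])
            proj_maps.append(p.reshape(H, W, cfg.d_model))
        tokens = concat(token_parts, axis=0)
        tokens = tokens + Tensor(_sinusoidal_pos(centers, cfg.d_model))

        # encoder over the multi-scale token set
        for layer in self.encoder_layers:
            maps = _split_levels(tokens, shapes, cfg.d_model)
            tokens = layer(tokens, centers, maps)
        memory = tokens

        # FGSP scoring of encoder output tokens
        class_logits, fg_logits = self.fgsp_head(memory)
        scores = fgsp_scores(class_logits.data, fg_logits.data)
        if cfg.use_fgsp:
            p_j = np.array([s.product for s in scores])
            kept = (select_foreground_tokens(scores, cfg.keep_ratio)
                    if cfg.keep_ratio < 1.0 else np.arange(len(scores)))
        else:
            p_j = np.array([s.class_prob for s in scores])
            kept = np.arange(len(scores))

        # encoder auxiliary predictions on kept tokens; top-Q become queries
        kept_memory = memory[kept]
        base_wh = 0.2 * (2.0 ** level_id[kept])
        base = np.stack([centers[kept, 0], centers[kept, 1], base_wh, base_wh], axis=1)
        enc_delta = self.enc_box_head(kept_memory)
        enc_boxes = sigmoid(enc_delta + Tensor(inverse_sigmoid(base)))
        enc_logits = class_logits[kept]

        n_q = min(cfg.n_queries, kept.size)
        top = np.argsort(-p_j[kept], kind="stable")[:n_q]
        query_content = self.query_proj(kept_memory[top])
        ref_boxes = enc_boxes.data[top].copy()

        # denoising branch
        dn_batch: DenoisingBatch | None = None
        if cfg.use_dn and training and targets is not None and \
                len(np.atleast_1d(targets.get("labels", []))) > 0:
            dn_batch = build_denoising_queries(
                targets["boxes"], targets["labels"], cfg.n_classes,
                n_matching_queries=n_q,
                box_noise_scale=cfg.dn_box_noise,
                label_flip_prob=cfg.dn_label_flip,
                n_groups=cfg.dn_groups, rng=rng,
            )
            dn_content = self.label_embed[dn_batch.labels]
            query_content = concat([query_content, dn_content], axis=0)
            ref_boxes = np.concatenate([ref_boxes, dn_batch.boxes], axis=0)
            attn_mask = dn_batch.attn_mask
        else:
            attn_mask = None

        # soft masks on the memory levels used by decoder cross-attention
        memory_maps = _split_levels(memory, shapes, cfg.d_model)
        soft_masks = None
        if self.maskmlp is not None and cfg.maskmlp_place == "encoder":
            soft_masks = [self.maskmlp(m) for m in memory_maps]
            memory_maps = [sm.apply(m) for sm, m in zip(soft_masks, memory_maps)]
        elif self.maskmlp_backbone is not None:
            soft_masks = soft_masks_bb

        # decoder with iterative box refinement
        q = query_content
        layer_records = []
        for layer in self.decoder_layers:
            q, logits, boxes = layer(q, ref_boxes, memory_maps, rng,
                                     training, attn_mask)
            layer_records.append((logits, boxes))
            ref_boxes = boxes.data.copy()

        # split matching / denoising parts and match each layer
        decoder_layers = []
        dn_out = None
        gt_boxes = (np.asarray(targets["boxes"], dtype=float).reshape(-1, 4)
                    if targets is not None else np.zeros((0, 4)))
        gt_labels = (np.asarray(targets["labels"], dtype=int).reshape(-1)
                     if targets is not None else np.zeros(0, dtype=int))
        for li, (logits, boxes) in enumerate(layer_records):
            m_logits = logits[:n_q]
            m_boxes = boxes[:n_q]
            if gt_boxes.shape[0] > 0 and n_q >= gt_boxes.shape[0]:
                probs = 1.0 / (1.0 + np.exp(-m_logits.data))
                matched = hungarian_match(m_boxes.data, probs, gt_boxes,
                                          gt_labels, cfg.match_weights)
            else:
                matched = np.zeros(0, dtype=int)
            decoder_layers.append({"logits": m_logits, "boxes": m_boxes,
                                   "matched_pred_idx": matched})
            if dn_batch is not None and li == len(layer_records) - 1:
                dn_out = {"logits": logits[n_q:], "boxes": boxes[n_q:],
                          "gt_index": dn_batch.gt_index}

        enc_matched = np.zeros(0, dtype=int)
        if gt_boxes.shape[0] > 0 and kept.size >= gt_boxes.shape[0]:
            enc_probs = 1.0 / (1.0 + np.exp(-enc_logits.data))
            enc_matched = hungarian_match(enc_boxes.data, enc_probs, gt_boxes,
                                          gt_labels, cfg.match_weights)

        final_logits, final_boxes = layer_records[-1]
        pred_scores = 1.0 / (1.0 + np.exp(-final_logits.data[:n_q]))
        outputs = {
            "n_classes": cfg.n_classes,
            "decoder_layers": decoder_layers,
            "dn": dn_out,
            "enc": {"logits": enc_logits, "boxes": enc_boxes,
                    "matched_pred_idx": enc_matched},
            "soft_masks": soft_masks,
            "fg_logits": fg_logits,
            "token_centers": centers,
            "token_level": level_id,
            "level_shapes": shapes,
            "pred_scores": pred_scores,                      # (Q, n_classes)
            "pred_boxes": final_boxes.data[:n_q].copy(),     # normalised cxcywh
            "pred_boxes_xyxy": cxcywh_to_xyxy(final_boxes.data[:n_q]),
        }
        return outputs

    __call__ = forward

    # ------------------------------------------------------------------
    def prepare_targets(self, annotations, image_shape: tuple[int, int],
                        masks: dict | None = None,
                        category_index: dict | None = None) -> dict:
        """Build the target dict for one image from COCO-style annotations.

        Boxes go to normalised (cx, cy, w, h); ``fg_labels`` marks tokens
        whose centre lies inside any ground-truth box; ``level_masks``
        pools the union of instance masks to each pyramid level grid.
        """
        H, W = image_shape
        cfg = self.config
        boxes = []
        labels = []
        for a in annotations:
            x, y, w, h = a.bbox
            boxes.append([(x + w / 2) / W, (y + h / 2) / H, w / W, h / H])
            if category_index is not None:
                labels.append(category_index[a.category_id])
            else:
                labels.append(0)
        boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
        labels = np.asarray(labels, dtype=int)

        shapes = _level_shapes(H, W, cfg.n_levels)
        centers, _ = self._token_geometry(shapes)
        fg = np.zeros(centers.shape[0])
        for b in boxes:
            x0, y0 = b[0] - b[2] / 2, b[1] - b[3] / 2
            x1, y1 = b[0] + b[2] / 2, b[1] + b[3] / 2
            inside = ((centers[:, 0] >= x0) & (centers[:, 0] <= x1)
                      & (centers[:, 1] >= y0) & (centers[:, 1] <= y1))
            fg[inside] = 1.0

        level_masks = None
        if masks is not None:
            union = np.zeros((H, W), dtype=bool)
            for a in annotations:
                if a.id in masks:
                    union |= masks[a.id]
            level_masks = []
            for (h_l, w_l) in shapes:
                ys = np.minimum((np.arange(H) * h_l) // H, h_l - 1)
                xs = np.minimum((np.arange(W) * w_l) // W, w_l - 1)
                acc = np.zeros((h_l, w_l))
                cnt = np.zeros((h_l, w_l))
                np.add.at(acc, (ys[:, None].repeat(W, 1), xs[None, :].repeat(H, 0)),
                          union.astype(float))
                np.add.at(cnt, (ys[:, None].repeat(W, 1), xs[None, :].repeat(H, 0)),
                          1.0)
                level_masks.append((acc / np.maximum(cnt, 1)) >= 0.5)

        return {"boxes": boxes, "labels": labels, "fg_labels": fg,
                "level_masks": level_masks}

    def predict(self, image: np.ndarray, score_threshold: float = 0.0) -> list[dict]:
        """Inference: list of {score, label, box_xyxy (normalised)}."""
        out = self.forward(image, training=False)
        dets = []
        for q in range(out["pred_scores"].shape[0]):
            label = int(np.argmax(out["pred_scores"][q]))
            score = float(out["pred_scores"][q, label])
            if score >= score_threshold:
                dets.append({"score": score, "label": label,
                             "box_xyxy": out["pred_boxes_xyxy"][q]})
        dets.sort(key=lambda d: -d["score"])
        return dets


def _split_levels(tokens: Tensor, shapes, d: int) -> list[Tensor]:
    maps = []
    off = 0
    for (H, W) in shapes:
        maps.append(tokens[off:off + H * W].reshape(H, W, d))
        off += H * W
    return maps


def _level_shapes(H: int, W: int, n_levels: int) -> list[tuple[int, int]]:
    shapes = []
    h, w = H, W
    for s in (2, 2, 2):  # stride 8 base
        h, w = -(-h // 2), -(-w // 2)
    for _ in range(n_levels):
        shapes.append((h, w))
        h, w = -(-h // 2), -(-w // 2)
    return shapes


def save_checkpoint(model: KeyFgDetector, path: str | Path) -> None:
    """Single-file checkpoint: weights + config + config hash."""
    state = model.state_dict()
    path = Path(path)
    np.savez(path, *state,
             config=json.dumps(asdict(model.config), default=str),
             config_hash=model.config.config_hash())


def load_checkpoint(path: str | Path, config: ModelConfig) -> KeyFgDetector:
    data = np.load(Path(path).with_suffix(".npz"), allow_pickle=False)
    if str(data["config_hash"]) != config.config_hash():
        raise ValueError("checkpoint config hash does not match given config")
    model = KeyFgDetector(config)
    arrays = [data[f"arr_{i}"] for i in range(len(model.parameters()))]
    model.load_state_dict(arrays)
    return model
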