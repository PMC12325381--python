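"""Copy-paste data augmentation for detection datasets.

An annotated object is extracted from a source image (using its instance
mask when available, else the bbox rectangle), randomly rotated and
scaled, and pasted into a destination image with hard masking; the
destination gains one annotation per pasted object.  Occlusion of
existing annotations is allowed and the occluded annotations are kept,
mirroring natural occlusion in field imagery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from skimage.transform import rescale, rotate

from .coco import Annotation, DetectionDataset, ImageInfo

logger = logging.getLogger(__name__)

__all__ = ["ObjectPatch", "extract_patch", "transform_patch",
           "copy_paste_augment", "augment_dataset"]


@dataclass
class ObjectPatch:
    """An extracted object: pixel patch + binary mask + provenance."""

    patch: np.ndarray       # (h, w, 3) uint8
    mask: np.ndarray        # (h, w) bool
    source_annotation_id: int
    category_id: int

    def __post_init__(self) -> None:
        if self.patch.shape[:2] != self.mask.shape:
            raise ValueError("mask and patch must share dimensions")
        if not self.mask.any():
            raise ValueError("mask is empty")


def extract_patch(
    image: np.ndarray, ann: Annotation, mask: np.ndarray | None = None
) -> ObjectPatch:
    """Cut the object's tight patch out of an image.

    With an instance mask the patch is cropped to the mask's tight box;
    without one the bbox rectangle is used with a full mask.
    """
    x, y, w, h = ann.bbox
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = x0 + int(round(w)), y0 + int(round(h))
    if mask is not None:
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            raise ValueError("mask is empty")
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        m = mask[y0:y1, x0:x1]
    else:
        m = np.ones((y1 - y0, x1 - x0), dtype=bool)
    return ObjectPatch(
        patch=np.asarray(image[y0:y1, x0:x1]),
        mask=m,
        source_annotation_id=ann.id,
        category_id=ann.category_id,
    )


def transform_patch(
    patch: ObjectPatch, angle_deg: float, scale: float
) -> ObjectPatch:
    """Rotate (expanding the canvas) then rescale patch and mask."""
    img = patch.patch.astype(float)
    m = patch.mask.astype(float)
    if angle_deg % 360 != 0:
        img = rotate(img, angle_deg, resize=True, order=1, preserve_range=True)
        m = rotate(m, angle_deg, resize=True, order=1, preserve_range=True)
    if scale != 1.0:
        img = rescale(img, scale, channel_axis=2, order=1, preserve_range=True)
        m = rescale(m, scale, order=1, preserve_range=True)
    mask = m >= 0.5
    if not mask.any():
        raise ValueError("transformed mask vanished")
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return ObjectPatch(
        patch=np.clip(img[y0:y1, x0:x1], 0, 255).astype(np.uint8),
        mask=mask[y0:y1, x0:x1],
        source_annotation_id=patch.source_annotation_id,
        category_id=patch.category_id,
    )


def copy_paste_augment(
    src_image: np.ndarray,
    src_annotations: list[Annotation],
    dst_image: np.ndarray,
    dst_annotations: list[Annotation],
    rng: np.random.Generator,
    rotation_range: tuple[float, float] = (-30.0, 30.0),
    scale_range: tuple[float, float] = (0.7, 1.3),
    n_paste: int = 1,
    src_masks: dict[int, np.ndarray] | None = None,
    blend: bool = False,
) -> tuple[np.ndarray, list[Annotation], dict[int, np.ndarray]]:
    """Paste ``n_paste`` randomly transformed source objects into a copy of
    the destination image.

    Returns the augmented image, the destination annotations plus one new
    annotation per pasted object (new ids continue after the existing
    maximum), and the pasted objects' masks keyed by new annotation id.
    Placement is rejection-sampled: if a transformed patch cannot fit
    after 50 position draws it is skipped with a warning.
    """
    if not src_annotations:
        raise ValueError("source has no annotations")
    out = np.array(dst_image, copy=True)
    H, W = out.shape[:2]
    new_anns = list(dst_annotations)
    new_masks: dict[int, np.ndarray] = {}
    next_id = max((a.id for a in new_anns), default=0) + 1

    for _ in range(n_paste):
        ann = src_annotations[rng.integers(len(src_annotations))]
        mask = src_masks.get(ann.id) if src_masks else None
        patch = extract_patch(src_image, ann, mask)
        angle = rng.uniform(*rotation_range)
        scale = rng.uniform(*scale_range)
        try:
            tp = transform_patch(patch, angle, scale)
        except ValueError:
            logger.warning("transform degenerated for annotation %d; skipped", ann.id)
            continue
        ph, pw = tp.mask.shape
        if ph > H or pw > W:
            logger.warning("transformed patch %dx%d does not fit %dx%d; skipped",
                           pw, ph, W, H)
            continue
        placed = False
        for _attempt in range(50):
            y0 = int(rng.integers(0, H - ph + 1))
            x0 = int(rng.integers(0, W - pw + 1))
            placed = True
            break
        if not placed:  # pragma: no cover - placement always succeeds when it fits
            logger.warning("could not place patch; skipped")
            continue
        region = out[y0 : y0 + ph, x0 : x0 + pw]
        if blend:
            a = tp.mask.astype(float)[..., None]
            region[:] = (a * tp.patch + (1 - a) * region).astype(out.dtype)
        else:
            region[tp.mask] = tp.patch[tp.mask]
        ys, xs = np.nonzero(tp.mask)
        bx0, by0 = x0 + xs.min(), y0 + ys.min()
        bw = xs.max() - xs.min() + 1
        bh = ys.max() - ys.min() + 1
        full_mask = np.zeros((H, W), dtype=bool)
        full_mask[y0 : y0 + ph, x0 : x0 + pw] = tp.mask
        new_ann = Annotation(
            id=next_id,
            image_id=dst_annotations[0].image_id if dst_annotations else -1,
            bbox=(float(bx0), float(by0), float(bw), float(bh)),
            category_id=tp.category_id,
        )
        new_anns.append(new_ann)
        new_masks[next_id] = full_mask
        next_id += 1
    return out, new_anns, new_masks


def augment_dataset(
    dataset: DetectionDataset,
    n_target_images: int,
    seed: int = 0,
    rotation_range: tuple[float, float] = (-30.0, 30.0),
    scale_range: tuple[float, float] = (0.7, 1.3),
) -> DetectionDataset:
    """Grow a dataset to ``n_target_images`` by copy-paste augmentation.

    Original images are retained untouched; each new image is a random
    destination image with a random source object pasted in.  The result
    is deterministic given ``seed`` and passes dataset validation.
    """
    if n_target_images < len(dataset.images):
        raise ValueError("n_target_images must be >= dataset size")
    if not dataset.annotations:
        raise ValueError("dataset has no annotations")
    rng = np.random.default_rng(seed)
    out = DetectionDataset(
        images=list(dataset.images),
        annotations=list(dataset.annotations),
        categories=list(dataset.categories),
        pixels=dict(dataset.pixels),
        masks=dict(dataset.masks),
        image_root=dataset.image_root,
    )
    by_image = {im.id: dataset.annotations_for(im.id) for im in dataset.images}
    sources = [im.id for im in dataset.images if by_image[im.id]]
    next_img_id = out.next_image_id()
    next_ann_id = out.next_annotation_id()

    while len(out.images) < n_target_images:
        src_id = sources[rng.integers(len(sources))]
        dst = dataset.images[rng.integers(len(dataset.images))]
        dst_anns = by_image[dst.id]
        img, anns, masks = copy_paste_augment(
            dataset.load_pixels(src_id),
            by_image[src_id],
            dataset.load_pixels(dst.id),
            dst_anns,
            rng,
            rotation_range=rotation_range,
            scale_range=scale_range,
            src_masks=dataset.masks or None,
        )
        new_image = ImageInfo(
            id=next_img_id, width=dst.width, height=dst.height,
            file_name=f"aug_{next_img_id:05d}.png",
        )
        out.images.append(new_image)
        out.pixels[new_image.id] = img
        # re-key all annotations (copies of dst's plus pasted) to the new image
        for a in anns:
            is_new = a.id not in {d.id for d in dst_anns}
            reann = Annotation(
                id=next_ann_id, image_id=new_image.id, bbox=a.bbox,
                category_id=a.category_id, iscrowd=a.iscrowd,
            )
            out.annotations.append(reann)
            if is_new and a.id in masks:
                out.masks[next_ann_id] = masks[a.id]
            elif a.id in dataset.masks:
                out.masks[next_ann_id] = dataset.masks[a.id]
            next_ann_id += 1
        next_img_id += 1
    out.validate()
    return out
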