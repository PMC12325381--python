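"""COCO-format detection dataset I/O, region extraction, and hold-out split.

Datasets follow the COCO detection dialect: one JSON file holding
``images``, ``annotations`` ([x, y, w, h] boxes, origin top-left) and
``categories`` arrays, with images stored as PNG/JPEG files referenced by
``file_name``.  The in-memory :class:`DetectionDataset` can additionally
carry pixel arrays and instance masks directly, which is how the
synthetic-scene generator hands data to downstream stages without disk
round-trips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageInfo",
    "Annotation",
    "Category",
    "DetectionDataset",
    "read_coco",
    "write_coco",
    "extract_regions",
    "holdout_split",
]


@dataclass
class ImageInfo:
    id: int
    width: int
    height: int
    file_name: str = ""


@dataclass
class Annotation:
    id: int
    image_id: int
    bbox: tuple[float, float, float, float]  # [x, y, w, h]
    category_id: int
    iscrowd: int = 0
    area: float | None = None

    def __post_init__(self) -> None:
        self.bbox = tuple(float(v) for v in self.bbox)
        if self.area is None:
            self.area = self.bbox[2] * self.bbox[3]


@dataclass
class Category:
    id: int
    name: str


@dataclass
class DetectionDataset:
    """In-memory COCO-style detection dataset.

    ``pixels`` maps image id -> (H, W, 3) uint8 array and ``masks`` maps
    annotation id -> (H, W) bool array; both are optional and used by the
    synthetic generator and augmenter.  ``image_root`` locates image files
    on disk when pixel arrays are not held in memory.
    """

    images: list[ImageInfo] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    categories: list[Category] = field(default_factory=list)
    pixels: dict[int, np.ndarray] = field(default_factory=dict)
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    image_root: Path | None = None

    def validate(self) -> None:
        image_ids = {im.id for im in self.images}
        if len(image_ids) != len(self.images):
            raise ValueError("duplicate image ids")
        ann_ids = [a.id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            dupes = sorted({i for i in ann_ids if ann_ids.count(i) > 1})
            raise ValueError(f"duplicate annotation ids: {dupes}")
        dims = {im.id: (im.width, im.height) for im in self.images}
        for a in self.annotations:
            if a.image_id not in image_ids:
                raise ValueError(
                    f"annotation {a.id} references missing image id {a.image_id}"
                )
            x, y, w, h = a.bbox
            W, H = dims[a.image_id]
            if not (x >= 0 and y >= 0 and w > 0 and h > 0 and x + w <= W and y + h <= H):
                raise ValueError(
                    f"annotation {a.id}: bbox {a.bbox} out of bounds for "
                    f"image {a.image_id} ({W}x{H})"
                )

    def annotations_for(self, image_id: int) -> list[Annotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def load_pixels(self, image_id: int) -> np.ndarray:
        """Return the (H, W, 3) uint8 pixel array for an image, from memory
        or from disk."""
        if image_id in self.pixels:
            return self.pixels[image_id]
        info = next(im for im in self.images if im.id == image_id)
        if self.image_root is None:
            raise ValueError(f"no pixels in memory and no image_root for image {image_id}")
        from PIL import Image

        arr = np.asarray(Image.open(Path(self.image_root) / info.file_name).convert("RGB"))
        return arr

    def next_annotation_id(self) -> int:
        return max((a.id for a in self.annotations), default=0) + 1

    def next_image_id(self) -> int:
        return max((im.id for im in self.images), default=0) + 1


def read_coco(path: str | Path) -> DetectionDataset:
    """Read a COCO-style JSON annotation file and validate the dataset."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed JSON in {path}: {e}") from e
    for key in ("images", "annotations", "categories"):
        if key not in raw:
            raise ValueError(f"missing key '{key}' in {path}")
    try:
        images = [
            ImageInfo(
                id=im["id"],
                width=im["width"],
                height=im["height"],
                file_name=im.get("file_name", ""),
            )
            for im in raw["images"]
        ]
        annotations = [
            Annotation(
                id=a["id"],
                image_id=a["image_id"],
                bbox=tuple(a["bbox"]),
                category_id=a["category_id"],
                iscrowd=a.get("iscrowd", 0),
                area=a.get("area"),
            )
            for a in raw["annotations"]
        ]
        categories = [Category(id=c["id"], name=c["name"]) for c in raw["categories"]]
    except KeyError as e:
        raise ValueError(f"missing field {e} in {path}") from e
    ds = DetectionDataset(
        images=images,
        annotations=annotations,
        categories=categories,
        image_root=path.parent,
    )
    ds.validate()
    return ds


def write_coco(dataset: DetectionDataset, path: str | Path) -> None:
    """Write a dataset as standard COCO JSON (category order preserved)."""
    dataset.validate()
    doc = {
        "images": [
            {"id": im.id, "width": im.width, "height": im.height, "file_name": im.file_name}
            for im in dataset.images
        ],
        "annotations": [
            {
                "id": a.id,
                "image_id": a.image_id,
                "bbox": list(a.bbox),
                "category_id": a.category_id,
                "iscrowd": a.iscrowd,
                "area": a.area,
            }
            for a in dataset.annotations
        ],
        "categories": [{"id": c.id, "name": c.name} for c in dataset.categories],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _box_slice(bbox: tuple[float, float, float, float]) -> tuple[slice, slice]:
    # rasterize: floor of x,y; round of w,h
    x, y, w, h = bbox
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    return slice(y0, y0 + int(round(h))), slice(x0, x0 + int(round(w)))


def extract_regions(image: np.ndarray, annotations, mode="whole_image_minus_boxes"):
    """Extract per-object foreground pixels and background pixels.

    Foreground of object ``j`` is its bounding-box interior (round(w)·round(h)
    pixels).  In ``whole_image_minus_boxes`` mode the background is the
    image minus the union of all annotated boxes and is returned once; in
    ``local_surround`` mode each object gets its own background — the 3x
    dilated box minus the union of all boxes, clipped to the image — and a
    list is returned.

    Returns ``(fg_list, bg)`` where ``bg`` is an (N, 3) array or, in local
    mode, a list of such arrays (possibly empty, flagged not fatal).
    """
    mode = getattr(mode, "value", mode)
    img = np.asarray(image)
    H, W = img.shape[:2]
    flat = img.reshape(-1, img.shape[-1]) if img.ndim == 3 else img.reshape(-1, 1)

    box_mask = np.zeros((H, W), dtype=bool)
    fgs = []
    for a in annotations:
        ys, xs = _box_slice(a.bbox)
        if ys.start < 0 or xs.start < 0 or ys.stop > H or xs.stop > W:
            raise ValueError(f"annotation {a.id}: box outside image bounds")
        box_mask[ys, xs] = True
        fgs.append(img[ys, xs].reshape(-1, img.shape[-1] if img.ndim == 3 else 1))

    if mode == "whole_image_minus_boxes":
        bg = flat[~box_mask.ravel()]
        if bg.shape[0] == 0:
            logger.warning("background region is empty (boxes cover whole image)")
        return fgs, bg
    if mode == "local_surround":
        bgs = []
        for a in annotations:
            x, y, w, h = a.bbox
            cx, cy = x + w / 2.0, y + h / 2.0
            x0 = max(0, int(np.floor(cx - 1.5 * w)))
            x1 = min(W, int(np.ceil(cx + 1.5 * w)))
            y0 = max(0, int(np.floor(cy - 1.5 * h)))
            y1 = min(H, int(np.ceil(cy + 1.5 * h)))
            local = np.zeros((H, W), dtype=bool)
            local[y0:y1, x0:x1] = True
            local &= ~box_mask
            bg = flat[local.ravel()]
            if bg.shape[0] == 0:
                logger.warning("annotation %d: empty local background", a.id)
            bgs.append(bg)
        return fgs, bgs
    raise ValueError(f"unknown background mode {mode!r}")


def holdout_split(
    dataset: DetectionDataset, ratio: float = 0.7, seed: int = 0
) -> tuple[DetectionDataset, DetectionDataset]:
    """Image-level hold-out split (train fraction ``ratio``, default 7:3).

    Annotations follow their images; the split is deterministic given the
    seed.  Splitting by image rather than by annotation avoids leakage of
    object instances across the partition.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    if len(dataset.images) < 2:
        raise ValueError("need at least 2 images to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.images))
    n_train = int(round(ratio * len(dataset.images)))
    train_idx = set(order[:n_train].tolist())

    def subset(idx_filter) -> DetectionDataset:
        imgs = [im for i, im in enumerate(dataset.images) if idx_filter(i)]
        ids = {im.id for im in imgs}
        anns = [a for a in dataset.annotations if a.image_id in ids]
        return DetectionDataset(
            images=imgs,
            annotations=anns,
            categories=list(dataset.categories),
            pixels={k: v for k, v in dataset.pixels.items() if k in ids},
            masks={a.id: dataset.masks[a.id] for a in anns if a.id in dataset.masks},
            image_root=dataset.image_root,
        )

    return subset(lambda i: i in train_idx), subset(lambda i: i not in train_idx)
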