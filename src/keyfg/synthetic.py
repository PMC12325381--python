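"""Synthetic camouflage scene generator.

Produces annotated scenes whose foreground-background chromatic
similarity is controllable through a single parameter ``alpha``: object
colours are drawn from a palette whose component means are linearly
interpolated toward the background palette's means.  At ``alpha = 0``
(and palettes in disjoint RGB octants) objects are conspicuous, with
chi-square distance ``Tgc`` well above the 0.9 camouflage threshold; at
``alpha = 1`` object and background share their mean colours and ``Tgc``
falls below the threshold.  This emulates the chromatic-camouflage
structure of field pest imagery — camouflage here is colour-histogram
similarity, not texture similarity, so per-component standard deviations
(texture) are preserved under blending.

The default palettes mimic a green-vegetation background and a
brown/tan insect body, the situation the locust data presents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .coco import Annotation, Category, DetectionDataset, ImageInfo, write_coco

__all__ = [
    "Palette",
    "SceneSpec",
    "blend_palette",
    "compose_scene",
    "generate_dataset",
    "BACKGROUND_PALETTE",
    "OBJECT_PALETTE",
]


@dataclass(frozen=True)
class Palette:
    """Mixture of k Gaussian RGB components (means in [0, 255])."""

    means: np.ndarray    # (k, 3)
    stds: np.ndarray     # (k, 3)
    weights: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        stds = np.atleast_2d(np.asarray(self.stds, dtype=float))
        weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        s = weights.sum()
        if s <= 0:
            raise ValueError("weights must sum to a positive value")
        weights = weights / s
        if means.min() < 0 or means.max() > 255:
            raise ValueError("component means must lie in [0, 255]")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "stds", np.broadcast_to(stds, means.shape).copy())
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n RGB samples from the mixture, clipped to [0, 255]."""
        comp = rng.choice(self.k, size=n, p=self.weights)
        vals = rng.normal(self.means[comp], self.stds[comp])
        return np.clip(vals, 0, 255)


# Greenish vegetation background vs brown/tan insect body: component means
# sit in disjoint RGB octants (G-dominant vs R-dominant) so that alpha=0
# scenes are conspicuous.
BACKGROUND_PALETTE = Palette(
    means=np.array([[60.0, 130.0, 55.0], [95.0, 165.0, 80.0], [40.0, 95.0, 45.0]]),
    stds=np.full((3, 3), 12.0),
    weights=np.array([0.45, 0.35, 0.2]),
)
OBJECT_PALETTE = Palette(
    means=np.array([[195.0, 110.0, 50.0], [225.0, 160.0, 90.0], [160.0, 85.0, 40.0]]),
    stds=np.full((3, 3), 12.0),
    weights=np.array([0.45, 0.35, 0.2]),
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 128
    width: int = 128
    n_objects: int = 1
    shape: str = "blob"          # "ellipse" | "blob"
    alpha: float = 0.5           # 0 = conspicuous, 1 = fully blended
    noise_std: float = 4.0       # extra per-pixel texture noise
    min_radius: int = 10
    max_radius: int = 22
    allow_overlap: bool = False
    background: Palette = BACKGROUND_PALETTE
    objects: Palette = OBJECT_PALETTE

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown shape family {self.shape!r}")


def blend_palette(obj: Palette, bg: Palette, alpha: float) -> Palette:
    """Interpolate object component means toward the background palette's
    means; standard deviations (texture) are kept."""
    if obj.k != bg.k:
        raise ValueError("palettes must have the same number of components")
    means = (1 - alpha) * obj.means + alpha * bg.means
    return Palette(means=means, stds=obj.stds, weights=obj.weights)


def _object_mask(
    cy: float, cx: float, ry: float, rx: float, shape: str,
    H: int, W: int, rng: np.random.Generator,
) -> np.ndarray:
    yy, xx = np.mgrid[0:H, 0:W]
    theta = rng.uniform(0, np.pi)
    ca, sa = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    if shape == "ellipse":
        return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    # blob: ellipse with radial noise on 12 control points, mimicking an
    # irregular insect-body outline
    n_ctrl = 12
    bumps = rng.uniform(0.75, 1.25, size=n_ctrl)
    ang = np.arctan2(v / ry, u / rx)
    idx = (ang + np.pi) / (2 * np.pi) * n_ctrl
    i0 = np.floor(idx).astype(int) % n_ctrl
    i1 = (i0 + 1) % n_ctrl
    frac = idx - np.floor(idx)
    r_mod = bumps[i0] * (1 - frac) + bumps[i1] * frac
    rho = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    return rho <= r_mod


def compose_scene(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    """Render one scene.

    Returns the (H, W, 3) uint8 image and a list of annotation dicts with
    ``bbox`` ([x, y, w, h], the mask's tight box), ``mask`` ((H, W) bool)
    and ``category_id``.  Objects are placed fully inside the image and,
    unless ``allow_overlap``, without overlap by rejection sampling (100
    attempts, then the object is skipped with a warning).
    """
    H, W = spec.height, spec.width
    if 2 * spec.max_radius >= min(H, W):
        raise ValueError(
            f"object radius {spec.max_radius} too large for {W}x{H} image"
        )
    img = spec.background.sample(H * W, rng).reshape(H, W, 3)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)

    obj_palette = blend_palette(spec.objects, spec.background, spec.alpha)
    occupied = np.zeros((H, W), dtype=bool)
    annotations: list[dict] = []
    for _ in range(spec.n_objects):
        placed = False
        for _attempt in range(100):
            ry = rng.uniform(spec.min_radius, spec.max_radius)
            rx = rng.uniform(spec.min_radius, spec.max_radius)
            margin = max(ry, rx) * 1.3 + 1
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            mask = _object_mask(cy, cx, ry, rx, spec.shape, H, W, rng)
            if mask.sum() < 4:
                continue
            if not spec.allow_overlap and (mask & occupied).any():
                continue
            placed = True
            break
        if not placed:
            import logging

            logging.getLogger(__name__).warning(
                "could not place object without overlap after 100 attempts; skipping"
            )
            continue
        occupied |= mask
        n_px = int(mask.sum())
        img[mask] = obj_palette.sample(n_px, rng) + (
            rng.normal(0.0, spec.noise_std, size=(n_px, 3)) if spec.noise_std > 0 else 0.0
        )
        ys, xs = np.nonzero(mask)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        annotations.append(
            {
                "bbox": (float(x0), float(y0), float(x1 - x0 + 1), float(y1 - y0 + 1)),
                "mask": mask,
                "category_id": 1,
            }
        )
    return np.clip(img, 0, 255).astype(np.uint8), annotations


def generate_dataset(
    n_images: int,
    spec: SceneSpec = SceneSpec(),
    seed: int = 0,
    alphas=None,
) -> DetectionDataset:
    """Generate ``n_images`` annotated scenes as an in-memory dataset.

    ``alphas`` optionally gives a per-image alpha (or a sequence cycled
    over images) overriding ``spec.alpha``.  Fully deterministic given
    ``seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    ds = DetectionDataset(categories=[Category(id=1, name="object")])
    ann_id = 1
    for i in range(n_images):
        s = spec
        if alphas is not None:
            a = alphas[i % len(alphas)] if np.ndim(alphas) else float(alphas)
            s = replace(spec, alpha=float(a))
        img, anns = compose_scene(s, rng)
        image_id = i + 1
        ds.images.append(
            ImageInfo(id=image_id, width=s.width, height=s.height,
                      file_name=f"scene_{image_id:05d}.png")
        )
        ds.pixels[image_id] = img
        for a in anns:
            ds.annotations.append(
                Annotation(id=ann_id, image_id=image_id, bbox=a["bbox"],
                           category_id=a["category_id"])
            )
            ds.masks[ann_id] = a["mask"]
            ann_id += 1
    ds.validate()
    return ds


def save_dataset(ds: DetectionDataset, out_dir: str | Path) -> Path:
    """Write images (PNG), per-annotation masks (PNG) and COCO JSON."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for im in ds.images:
        Image.fromarray(ds.load_pixels(im.id)).save(out / im.file_name)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for ann_id, mask in ds.masks.items():
        Image.fromarray((mask.astype(np.uint8)) * 255).save(
            mask_dir / f"mask_{ann_id:06d}.png"
        )
    ann_path = out / "annotations.json"
    write_coco(ds, ann_path)
    return ann_path
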