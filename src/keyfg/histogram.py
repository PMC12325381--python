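"""Camouflage Degree (CD) quantification for detection datasets.

An object is *camouflaged* when the RGB colour distribution of its
foreground region is close to that of the background.  Per object we
compute ``Tgc``, the chi-square distance between the normalised
per-channel RGB histograms of foreground and background, summed over the
three channels.  At the dataset level the Camouflage Degree is the ratio
of objects with ``Tgc`` below a threshold (default 0.9) to those at or
above it; CD around or above 1 marks a camouflaged dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegionHistogram",
    "CamouflageScore",
    "CDConfig",
    "DatasetCDReport",
    "BackgroundMode",
    "build_region_histogram",
    "compute_tgc",
    "compute_cd",
    "score_dataset",
]


class BackgroundMode(str, Enum):
    """How the background region of an object is defined."""

    WHOLE_IMAGE_MINUS_BOXES = "whole_image_minus_boxes"
    LOCAL_SURROUND = "local_surround"


@dataclass(frozen=True)
class RegionHistogram:
    """Normalised per-channel RGB histogram of an image region.

    ``channels`` is a (3, B) array of bin probabilities; each row sums to
    one when the region is non-empty.
    """

    channels: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[0] != 3:
            raise ValueError(f"channels must be (3, B), got {ch.shape}")
        if np.any(ch < 0):
            raise ValueError("bin probabilities must be non-negative")
        if self.n_pixels > 0:
            sums = ch.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"channel probabilities must sum to 1, got {sums}")
        object.__setattr__(self, "channels", ch)

    @property
    def n_bins(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class CamouflageScore:
    """Per-object camouflage score: the 3-channel chi-square distance."""

    object_id: int
    tgc: float
    is_camouflaged: bool


@dataclass(frozen=True)
class CDConfig:
    """Configuration for dataset-level Camouflage Degree scoring."""

    n_bins: int = 32
    threshold: float = 0.9
    background_mode: BackgroundMode = BackgroundMode.WHOLE_IMAGE_MINUS_BOXES

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class DatasetCDReport:
    """Aggregate camouflage report: counts on either side of the threshold
    and their ratio CD = n_below / n_above."""

    n_below: int
    n_above: int
    cd: float
    scores: list[CamouflageScore] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_below": self.n_below,
            "n_above": self.n_above,
            "cd": self.cd,
            "scores": [
                {"id": s.object_id, "tgc": s.tgc, "is_camouflaged": s.is_camouflaged}
                for s in self.scores
            ],
        }


def build_region_histogram(pixels: np.ndarray, n_bins: int = 32) -> RegionHistogram:
    """Bin a region's RGB pixels into ``n_bins`` equal-width intervals per
    channel over [0, 256) and normalise counts to probabilities.

    Parameters
    ----------
    pixels : array-like, shape (N, 3)
        RGB values in [0, 255].  A single-channel column is replicated to
        three channels with a warning (grayscale imagery).
    n_bins : int
        Number of equal-width bins per channel; intervals are
        ``[i*256/B, (i+1)*256/B)`` with the last bin closing at 255.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty region")
    if px.ndim == 1:
        px = px[:, None]
    if px.shape[1] == 1:
        logger.warning("grayscale region: replicating single channel to RGB")
        px = np.repeat(px, 3, axis=1)
    if px.shape[1] != 3:
        raise ValueError(f"expected RGB pixels (N, 3), got shape {px.shape}")
    if px.min() < 0 or px.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    edges = np.arange(n_bins + 1) * (256.0 / n_bins)
    hists = np.empty((3, n_bins), dtype=float)
    n = px.shape[0]
    for c in range(3):
        counts, _ = np.histogram(px[:, c], bins=edges)
        hists[c] = counts / n
    return RegionHistogram(channels=hists, n_pixels=n)


def compute_tgc(fg: RegionHistogram, bg: RegionHistogram) -> float:
    """Chi-square distance between foreground and background histograms,
    summed over the three channels.

    Per channel: ``sum_i (h1(i) - h2(i))^2 / (h1(i) + h2(i))``, skipping
    bins where both probabilities are zero.  Bounded by 2 per channel,
    hence by 6 in total.
    """
    if fg.n_bins != bg.n_bins:
        raise ValueError(
            f"histogram bin counts differ: {fg.n_bins} vs {bg.n_bins}"
        )
    h1, h2 = fg.channels, bg.channels
    denom = h1 + h2
    num = (h1 - h2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def compute_cd(
    scores: Sequence[CamouflageScore], threshold: float = 0.9
) -> DatasetCDReport:
    """Dataset Camouflage Degree: ratio of object counts below vs at-or-
    above the ``Tgc`` threshold."""
    scores = list(scores)
    if not scores:
        raise ValueError("scores must be non-empty")
    n_below = sum(1 for s in scores if s.tgc < threshold)
    n_above = len(scores) - n_below
    if n_above == 0:
        raise CDUndefinedError(n_below, n_above)
    return DatasetCDReport(
        n_below=n_below, n_above=n_above, cd=n_below / n_above, scores=scores
    )


class CDUndefinedError(ZeroDivisionError):
    """Raised when no object scores at or above the threshold."""

    def __init__(self, n_below: int, n_above: int) -> None:
        self.n_below = n_below
        self.n_above = n_above
        super().__init__(
            f"CD undefined: no conspicuous objects (n_below={n_below}, n_above={n_above})"
        )


def score_dataset(dataset, config: CDConfig = CDConfig()) -> DatasetCDReport:
    """Score every annotation of a detection dataset and aggregate to CD.

    Foreground = bounding-box interior; background per ``config.background_mode``
    (whole image minus the union of all annotated boxes, or a 3x dilated
    local surround).  Objects whose background region is empty are skipped
    with a warning and excluded from the counts.
    """
    from .coco import extract_regions

    if not dataset.annotations:
        raise ValueError("dataset has no annotations")
    scores: list[CamouflageScore] = []
    for image in dataset.images:
        anns = [a for a in dataset.annotations if a.image_id == image.id and not a.iscrowd]
        if not anns:
            continue
        pixels = dataset.load_pixels(image.id)
        fgs, bg = extract_regions(pixels, anns, mode=config.background_mode)
        local = config.background_mode == BackgroundMode.LOCAL_SURROUND
        for j, (ann, fg_px) in enumerate(zip(anns, fgs)):
            bg_px = bg[j] if local else bg
            if bg_px.shape[0] == 0:
                logger.warning(
                    "annotation %d: empty background region, skipped", ann.id
                )
                continue
            fg_hist = build_region_histogram(fg_px, config.n_bins)
            bg_hist = build_region_histogram(bg_px, config.n_bins)
            tgc = compute_tgc(fg_hist, bg_hist)
            scores.append(
                CamouflageScore(
                    object_id=ann.id,
                    tgc=tgc,
                    is_camouflaged=tgc < config.threshold,
                )
            )
    if not scores:
        raise ValueError("no scorable annotations (all skipped)")
    try:
        return compute_cd(scores, config.threshold)
    except CDUndefinedError:
        # report counts anyway, with an undefined (infinite) ratio
        return DatasetCDReport(
            n_below=len(scores), n_above=0, cd=float("inf"), scores=scores
        )
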