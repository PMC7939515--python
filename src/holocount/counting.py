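"""Probability map -> cell count post-processing chain.

The chain is: threshold at 0.5 (strictly greater), morphological opening with
a radius-3 disk (removes speckle-sized false positives and smooths edges),
connected-component labeling, exclusion of components that touch the frame
boundary with area < 40 px (partial cells at the edge that cannot be counted
reliably; the same rule must be applied to the ground truth), and finally the
count as the maximum label.  Each stage is pure and exposed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "PostprocessConfig",
    "binarize",
    "open_mask",
    "label_components",
    "exclude_border_small",
    "count_cells",
    "count_from_probability",
    "postprocess_truth",
]


@dataclass(frozen=True)
class PostprocessConfig:
    threshold: float = 0.5
    opening_radius: int = 3
    border_min_area: int = 40
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.opening_radius < 0 or self.border_min_area < 0:
            raise ValueError("opening_radius and border_min_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground where the probability is strictly greater than the threshold."""
    return np.asarray(prob) > threshold


def open_mask(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Morphological opening with the Euclidean disk {dx^2 + dy^2 <= r^2}."""
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndimage.binary_opening(mask, structure=disk(radius).astype(bool))


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in first-encounter raster-scan order."""
    flat = labels.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return labels
    first_seen = {}
    for v in nz:
        if v not in first_seen:
            first_seen[int(v)] = len(first_seen) + 1
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for old, new in first_seen.items():
        lut[old] = new
    return lut[labels]


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling; labels 1..K in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    labels, _ = ndimage.label(mask, structure=_structure(connectivity))
    return _relabel_raster_order(labels.astype(np.int32))


def exclude_border_small(
    labels: np.ndarray, min_area: int = 40, connectivity: int = 8
) -> np.ndarray:
    """Drop components that touch the frame boundary AND have area < min_area.

    Interior components are kept regardless of size; border components at or
    above the area threshold are kept too.  Survivors are relabeled
    contiguously (raster order) so the maximum label remains the count.
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    areas = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    border_labels = np.unique(labels[border & (labels > 0)])
    drop = [lab for lab in border_labels if areas[lab] < min_area]
    out = labels.copy()
    if drop:
        out[np.isin(out, drop)] = 0
    return _relabel_raster_order(out)


def count_cells(labels: np.ndarray) -> int:
    """The maximum value of a contiguously labeled map is the cell count."""
    return int(np.asarray(labels).max(initial=0))


def count_from_probability(
    prob: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()
) -> tuple[int, np.ndarray]:
    """Full chain: binarize -> open -> label -> border/small exclusion -> count."""
    mask = binarize(prob, cfg.threshold)
    mask = open_mask(mask, cfg.opening_radius)
    labels = label_components(mask, cfg.connectivity)
    labels = exclude_border_small(labels, cfg.border_min_area, cfg.connectivity)
    return count_cells(labels), labels


def postprocess_truth(mask: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Label a ground-truth mask with the same border/small exclusion as the
    prediction (no threshold or opening: the truth is already a clean mask)."""
    labels = label_components(np.asarray(mask, dtype=bool), cfg.connectivity)
    return exclude_border_small(labels, cfg.border_min_area, cfg.connectivity)
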