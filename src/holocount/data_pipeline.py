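"""Normalization, augmentation, padding/resizing and fold splitting.

Turns (hologram, mask) pairs into network-ready arrays: holograms are
standardized with mean/std pooled over the *training* images only, training
pairs are geometrically augmented with identical transforms on image and mask,
and every input is brought to the network's square input size (resize down,
zero-pad up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "NormStats",
    "FoldSplit",
    "AugmentSpec",
    "IDENTITY_AUGMENT",
    "compute_norm_stats",
    "normalize",
    "denormalize",
    "augment",
    "pad_or_resize_to_input",
    "split_folds",
]


@dataclass(frozen=True)
class NormStats:
    """Pooled pixel mean and population (1/N) standard deviation."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be positive")


def compute_norm_stats(train_images: list[np.ndarray]) -> NormStats:
    """Pool all pixels of the training images into one mean/std.

    Uses the population (ddof=0) standard deviation.  Validation and test
    images must be normalized with the stats returned here, never their own.
    """
    if len(train_images) == 0:
        raise ValueError("need at least one training image")
    pixels = np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in train_images])
    mean = float(pixels.mean())
    std = float(pixels.std())
    if std == 0.0:
        raise ValueError(
            "training pixels are all identical (std = 0); add noise to the "
            "simulation or disable normalization"
        )
    return NormStats(mean=mean, std=std)


def normalize(img: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(img, dtype=np.float64) - stats.mean) / stats.std


def denormalize(img: np.ndarray, stats: NormStats) -> np.ndarray:
    """Inverse of :func:`normalize` (normalization is affine and invertible)."""
    return np.asarray(img, dtype=np.float64) * stats.std + stats.mean


@dataclass(frozen=True)
class AugmentSpec:
    """Geometric augmentation ranges.

    The families (crop, resize, translation, rotation, flip) are fixed; the
    magnitudes here are deliberately conservative so cells stay intact:
    per-axis flips with probability 0.5, any multiple-of-90 rotation, an
    additional small-angle rotation within +-15 degrees, translation up to 10%
    of the side, and crop-then-resize with scale in [0.8, 1.0].
    """

    flip_horizontal_p: float = 0.5
    flip_vertical_p: float = 0.5
    rot90: bool = True
    max_rotate_deg: float = 15.0
    max_translate_frac: float = 0.10
    scale_range: tuple[float, float] = (0.8, 1.0)


IDENTITY_AUGMENT = AugmentSpec(
    flip_horizontal_p=0.0,
    flip_vertical_p=0.0,
    rot90=False,
    max_rotate_deg=0.0,
    max_translate_frac=0.0,
    scale_range=(1.0, 1.0),
)


def _resize_pair(
    img: np.ndarray, mask: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    img_r = _sk_resize(img, shape, order=1, anti_aliasing=False, preserve_range=True)
    mask_r = _sk_resize(
        mask.astype(np.float64), shape, order=0, anti_aliasing=False, preserve_range=True
    )
    return img_r, mask_r > 0.5


def augment(
    img: np.ndarray,
    mask: np.ndarray,
    spec: AugmentSpec = AugmentSpec(),
    seed: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform chain identically to image and mask.

    The mask is warped with nearest-neighbour interpolation and re-binarized at
    0.5, so it stays strictly binary; rotations and translations expose borders
    filled with 0, consistent with the zero-padding convention.  Intended for
    training batches only.
    """
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)

    if rng.random() < spec.flip_horizontal_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < spec.flip_vertical_p:
        img, mask = img[::-1, :], mask[::-1, :]
    if spec.rot90:
        k = int(rng.integers(0, 4))
        img, mask = np.rot90(img, k), np.rot90(mask, k)
    if spec.max_rotate_deg > 0:
        angle = float(rng.uniform(-spec.max_rotate_deg, spec.max_rotate_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        mask = (
            ndimage.rotate(
                mask.astype(np.float64), angle, reshape=False, order=0, mode="constant", cval=0.0
            )
            > 0.5
        )
    if spec.max_translate_frac > 0:
        h, w = img.shape
        dy = float(rng.uniform(-spec.max_translate_frac, spec.max_translate_frac) * h)
        dx = float(rng.uniform(-spec.max_translate_frac, spec.max_translate_frac) * w)
        img = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
        mask = (
            ndimage.shift(mask.astype(np.float64), (dy, dx), order=0, mode="constant", cval=0.0)
            > 0.5
        )
    lo, hi = spec.scale_range
    if (lo, hi) != (1.0, 1.0):
        scale = float(rng.uniform(lo, hi))
        h, w = img.shape
        ch, cw = max(1, round(h * scale)), max(1, round(w * scale))
        if ch > h or cw > w:
            raise ValueError("crop larger than image (scale_range must be <= 1)")
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        img, mask = _resize_pair(img[y0 : y0 + ch, x0 : x0 + cw], mask[y0 : y0 + ch, x0 : x0 + cw], (h, w))
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def pad_or_resize_to_input(
    img: np.ndarray,
    mask: np.ndarray | None,
    target: int | tuple[int, int],
    divisor: int = 16,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Bring an image (and optional mask) to the network input size.

    Inputs larger than ``target`` (in either dimension) are resized down
    (bilinear for the image, nearest for the mask); smaller inputs are
    zero-padded symmetrically, centring the original content.  ``target`` must
    be divisible by ``divisor`` (2**(depth-1) of the network, 16 for the
    default five-level model).
    """
    th, tw = (target, target) if isinstance(target, int) else target
    if th % divisor or tw % divisor:
        raise ValueError(
            f"target size ({th}, {tw}) must be divisible by {divisor} so every "
            "pooling level halves cleanly"
        )
    img = np.asarray(img, dtype=np.float64)
    mask_arr = None if mask is None else np.asarray(mask, dtype=bool)
    h, w = img.shape
    if h > th or w > tw:
        scale_shape = (min(h, th), min(w, tw))
        if mask_arr is None:
            img = _sk_resize(img, scale_shape, order=1, anti_aliasing=True, preserve_range=True)
        else:
            img, mask_arr = _resize_pair(img, mask_arr, scale_shape)
        h, w = img.shape
    if h < th or w < tw:
        py, px = th - h, tw - w
        pad = ((py // 2, py - py // 2), (px // 2, px - px // 2))
        img = np.pad(img, pad, mode="constant", constant_values=0.0)
        if mask_arr is not None:
            mask_arr = np.pad(mask_arr, pad, mode="constant", constant_values=False)
    return img, mask_arr


@dataclass(frozen=True)
class FoldSplit:
    """k-fold assignment: image id -> fold index in [0, k)."""

    k: int
    assignments: dict

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [i for i, f in self.assignments.items() if f != fold]


def split_folds(manifest: pd.DataFrame | list, k: int, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin k-fold assignment.

    Folds are disjoint, cover every id, and differ in size by at most one.
    ``manifest`` may be the simulator's manifest DataFrame (row index = id) or
    any list of hashable ids.
    """
    if isinstance(manifest, pd.DataFrame):
        ids = list(manifest.index)
    else:
        ids = list(manifest)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    assignments = {ids[int(j)]: int(pos % k) for pos, j in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments)
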