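"""Synthetic chest phantoms: low-contrast blurred ellipsoidal lesions inside a
lung-like background.

The generator emulates the structure of a semi-supervised pneumonia-CT corpus:
a small labeled pool, a large unlabeled pool, and lesions that are small,
low-contrast and blurred at their boundaries.  Intensities are normalized to
[0, 1].  Everything is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import LabelMask, Volume3D


class GenerationError(RuntimeError):
    """Lesion placement failed after the bounded number of retries."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic volume.

    contrast is the intensity offset of lesion over lung tissue before
    boundary blurring; blur_sigma (voxels) smooths the intensity field only,
    never the mask, producing the blurred-boundary appearance.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    n_lesions: int = 2
    radius_range: tuple[float, float] = (3.0, 6.0)
    contrast: float = 0.2
    blur_sigma: float = 1.0
    noise: float = 0.05
    seed: int = 0
    max_placement_attempts: int = 100

    def __post_init__(self):
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"radius range must be positive and ordered, got {self.radius_range}")
        if hi >= min(self.shape) / 2:
            raise ValueError(
                f"max radius {hi} must be < half the min grid axis {min(self.shape) / 2}"
            )
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass
class DatasetSplit:
    """Labeled / unlabeled / validation / test pools of phantom cases."""

    labeled: list[tuple[Volume3D, LabelMask]]
    unlabeled: list[Volume3D]
    validation: list[tuple[Volume3D, LabelMask]]
    test: list[tuple[Volume3D, LabelMask]]


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _lung_fields(shape) -> tuple[np.ndarray, list[tuple]]:
    """Two lung ellipsoids inside a body ellipsoid; returns union mask + params."""
    h, w, d = shape
    lungs = []
    for wc in (0.32, 0.68):
        center = (0.5 * h, wc * w, 0.5 * d)
        semi = (0.34 * h, 0.17 * w, 0.40 * d)
        lungs.append((center, semi))
    union = np.zeros(shape, dtype=bool)
    for c, s in lungs:
        union |= _ellipsoid_mask(shape, c, s)
    return union, lungs


def make_phantom(cfg: PhantomConfig) -> tuple[Volume3D, LabelMask]:
    """Generate one (volume, mask) pair; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.shape)
    h, w, d = shape

    # body / lung anatomy
    body = _ellipsoid_mask(shape, (0.5 * h, 0.5 * w, 0.5 * d), (0.49 * h, 0.49 * w, 0.52 * d))
    lung_union, lungs = _lung_fields(shape)
    img = np.full(shape, 0.15, dtype=np.float64)      # air outside the body
    img[body] = 0.55                                   # soft tissue
    img[lung_union] = 0.30                             # aerated lung

    # smooth low-frequency background texture
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=max(2.0, min(shape) / 6))
    scale = np.abs(lowfreq).max()
    if scale > 0:
        img += 0.04 * lowfreq / scale

    # lesions: ellipsoids with centres inside a lung field, fully inside the grid
    mask = np.zeros(shape, dtype=np.int16)
    lo, hi = cfg.radius_range
    for _ in range(cfg.n_lesions):
        placed = False
        for _attempt in range(cfg.max_placement_attempts):
            semi = rng.uniform(lo, hi, size=3)
            center = rng.uniform(semi, np.array(shape) - semi)
            cidx, sidx = lungs[rng.integers(len(lungs))]
            inside = sum(((c - cc) / ss) ** 2 for c, cc, ss in zip(center, cidx, sidx)) <= 1.0
            if not inside:
                continue
            les = _ellipsoid_mask(shape, center, semi)
            mask[les] = 1
            img[les] += cfg.contrast
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place a lesion after {cfg.max_placement_attempts} attempts "
                f"(shape {shape}, radii {cfg.radius_range})"
            )

    # blur the intensity field (not the mask): blurred lesions and boundaries
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.blur_sigma)
    if cfg.noise > 0:
        img += rng.normal(0.0, cfg.noise, shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return Volume3D(img), LabelMask(mask, num_classes=2)


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s % (2 ** 31)) for s in ss.generate_state(n, dtype=np.uint64)]


def make_split(
    cfg: PhantomConfig,
    n_labeled: int,
    n_unlabeled: int,
    n_val: int,
    n_test: int,
    seed: int,
) -> DatasetSplit:
    """Disjoint labeled/unlabeled/val/test pools with independent phantom seeds."""
    for name, n in (("n_labeled", n_labeled), ("n_unlabeled", n_unlabeled),
                    ("n_val", n_val), ("n_test", n_test)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    total = n_labeled + n_unlabeled + n_val + n_test
    seeds = _child_seeds(seed, total)
    items = [make_phantom(replace(cfg, seed=s)) for s in seeds]
    i = 0
    labeled = items[i:i + n_labeled]; i += n_labeled
    unlabeled = [v for v, _ in items[i:i + n_unlabeled]]; i += n_unlabeled
    val = items[i:i + n_val]; i += n_val
    test = items[i:i + n_test]
    return DatasetSplit(labeled, unlabeled, val, test)


def augment(
    vol: Volume3D,
    mask: Optional[LabelMask],
    seed: int,
    flip_prob: float = 0.5,
    noise_std: float = 0.1,
) -> tuple[Volume3D, Optional[LabelMask]]:
    """Random axis flips (applied to volume and mask alike) plus additive
    Gaussian intensity noise on the volume only.  Deterministic given seed."""
    if mask is not None and mask.shape != vol.shape:
        raise ValueError(f"volume/mask shape mismatch: {vol.shape} vs {mask.shape}")
    rng = np.random.default_rng(seed)
    img = vol.intensities.copy()
    lab = None if mask is None else mask.labels.copy()
    for axis in range(3):
        if rng.random() < flip_prob:
            img = np.flip(img, axis=axis)
            if lab is not None:
                lab = np.flip(lab, axis=axis)
    if noise_std > 0:
        img = img + rng.normal(0.0, noise_std, img.shape).astype(np.float32)
    out_mask = None if lab is None else LabelMask(np.ascontiguousarray(lab), mask.num_classes, mask.spacing)
    return Volume3D(np.ascontiguousarray(img), vol.spacing), out_mask
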