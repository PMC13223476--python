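"""Overlap and surface-distance metrics for binary 3-D masks.

Conventions, stated once:

* boundary voxels are foreground voxels with at least one background
  6-neighbour; the grid border counts as background;
* distances are Euclidean between boundary voxel centres, in voxel units by
  default or mm when a spacing is supplied;
* both-empty masks: dice/jaccard/nsd = 1.0, adb/hd95 undefined (error);
* NSD is two-sided, (|B_P within tau of B_G| + |B_G within tau of B_P|) /
  (|B_P| + |B_G|); a one-sided variant is selectable;
* ADB is the mean of the two directed mean nearest-boundary distances;
* HD95 is the 95th linear-interpolation percentile of the pooled directed
  nearest-boundary distances of both surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


class EmptyMaskError(ValueError):
    """A surface-distance metric was requested for an empty mask."""


@dataclass
class BoundarySet:
    """Coordinates (K, 3) of a mask's boundary voxels."""

    coords: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self):
        return len(self.coords)

    @property
    def physical(self) -> np.ndarray:
        return self.coords * np.asarray(self.spacing)


@dataclass
class MetricsReport:
    dice: float
    jaccard: float
    nsd: float
    adb: Optional[float]
    hd95: Optional[float]
    tau: float


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return p.astype(bool), g.astype(bool)


def dice(p, g) -> float:
    p, g = _check_pair(p, g)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, g).sum()) / denom


def jaccard(p, g) -> float:
    p, g = _check_pair(p, g)
    union = int(np.logical_or(p, g).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(p, g).sum()) / union


def extract_boundary(mask, spacing=(1.0, 1.0, 1.0)) -> BoundarySet:
    """Foreground voxels with a background 6-neighbour (border = background)."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3-D, got ndim={m.ndim}")
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    boundary = m & ~interior
    coords = np.argwhere(boundary)
    return BoundarySet(coords, m.shape, tuple(float(s) for s in spacing))


def _directed_distances(src: BoundarySet, dst: BoundarySet) -> np.ndarray:
    """Nearest-neighbour distance from each src boundary voxel to dst's set."""
    tree = cKDTree(dst.physical)
    d, _ = tree.query(src.physical, k=1)
    return np.asarray(d, dtype=float)


def nsd(p, g, tau: float = 1.0, spacing=(1.0, 1.0, 1.0), two_sided: bool = True) -> float:
    """Normalized surface dice: boundary fraction within tau of the other surface."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    p, g = _check_pair(p, g)
    bp = extract_boundary(p, spacing)
    bg = extract_boundary(g, spacing)
    if len(bp) == 0 and len(bg) == 0:
        return 1.0
    if len(bp) == 0 or len(bg) == 0:
        return 0.0
    d_pg = _directed_distances(bp, bg)
    hits = int((d_pg <= tau + 1e-9).sum())
    total = len(bp)
    if two_sided:
        d_gp = _directed_distances(bg, bp)
        hits += int((d_gp <= tau + 1e-9).sum())
        total += len(bg)
    return hits / total


def adb(p, g, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average distance of boundaries: mean of the two directed mean distances."""
    p, g = _check_pair(p, g)
    if not p.any() or not g.any():
        raise EmptyMaskError("adb is undefined for an empty mask")
    bp = extract_boundary(p, spacing)
    bg = extract_boundary(g, spacing)
    d_pg = _directed_distances(bp, bg)
    d_gp = _directed_distances(bg, bp)
    return 0.5 * (float(d_pg.mean()) + float(d_gp.mean()))


def hd95(p, g, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the pooled directed nearest-boundary distances."""
    p, g = _check_pair(p, g)
    if not p.any() or not g.any():
        raise EmptyMaskError("hd95 is undefined for an empty mask")
    bp = extract_boundary(p, spacing)
    bg = extract_boundary(g, spacing)
    pooled = np.concatenate([_directed_distances(bp, bg), _directed_distances(bg, bp)])
    return float(np.percentile(pooled, 95))


def evaluate_case(p, g, tau: float = 1.0, spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    p_arr, g_arr = _check_pair(p, g)
    both_nonempty = bool(p_arr.any()) and bool(g_arr.any())
    return MetricsReport(
        dice=dice(p_arr, g_arr),
        jaccard=jaccard(p_arr, g_arr),
        nsd=nsd(p_arr, g_arr, tau, spacing),
        adb=adb(p_arr, g_arr, spacing) if both_nonempty else None,
        hd95=hd95(p_arr, g_arr, spacing) if both_nonempty else None,
        tau=tau,
    )


def evaluate_split(pred_dir: str | Path, truth_dir: str | Path, tau: float = 1.0) -> pd.DataFrame:
    """Per-case metrics for matched NIfTI masks plus a mean/std aggregate.

    Cases are matched by filename; unmatched IDs raise with the full list.
    Returns a DataFrame with one row per case and trailing 'mean'/'std' rows.
    """
    from .volume import read_mask  # local import to avoid cycle at module load

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    preds = {f.name: f for f in sorted(pred_dir.glob("*.nii*"))}
    truths = {f.name: f for f in sorted(truth_dir.glob("*.nii*"))}
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise ValueError(f"unmatched case IDs between pred and truth: {unmatched}")
    if not preds:
        raise ValueError(f"no NIfTI masks found in {pred_dir}")
    rows = []
    for name in sorted(preds):
        pm = read_mask(preds[name])
        gm = read_mask(truths[name])
        rep = evaluate_case(pm.labels > 0, gm.labels > 0, tau, pm.spacing)
        rows.append({"case": name, "dice": rep.dice, "jaccard": rep.jaccard,
                     "nsd": rep.nsd, "adb": rep.adb, "hd95": rep.hd95})
    df = pd.DataFrame(rows).set_index("case")
    agg = pd.DataFrame({"mean": df.mean(numeric_only=True), "std": df.std(ddof=0, numeric_only=True)}).T
    return pd.concat([df, agg])
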