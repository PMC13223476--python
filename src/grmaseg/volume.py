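"""3-D volumes and label masks with NIfTI I/O and resampling.

Arrays are indexed (H, W, D), mirroring the convention that a chest-CT
training volume is stored as 160x160x32: two in-plane axes then the slice
axis.  On disk the array is written in exactly this order; the NIfTI affine
encodes the per-axis voxel spacing (mm) on its diagonal, so a round trip
through :func:`write_volume` / :func:`read_volume` is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for files or arrays that violate the 3-D volume contract."""


@dataclass
class Volume3D:
    """A scalar intensity grid plus per-axis physical spacing (mm/voxel)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise FormatError(f"volume must be 3-D, got ndim={self.intensities.ndim}")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def validate_network_ready(self) -> None:
        """The network downsamples three times: axes must be >=8 and divisible by 8."""
        for ax, n in enumerate(self.shape):
            if n < 8 or n % 8:
                raise FormatError(f"axis {ax} has size {n}; need >=8 and divisible by 8")


@dataclass
class LabelMask:
    """Integer label grid paired with a Volume3D; values in {0..num_classes-1}."""

    labels: np.ndarray
    num_classes: int = 2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"mask must be 3-D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise FormatError("mask values are not integral")
            self.labels = np.round(self.labels).astype(np.int16)
        self.labels = self.labels.astype(np.int16, copy=False)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.num_classes):
            raise FormatError(
                f"labels outside [0, {self.num_classes - 1}]: "
                f"range [{self.labels.min()}, {self.labels.max()}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), _affine(vol.spacing))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D NIfTI image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float32), spacing)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, num_classes: int = 2) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D NIfTI mask, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(data, num_classes=num_classes, spacing=spacing)


def _resample_coords(src: int, dst: int) -> np.ndarray:
    """Half-pixel-centre sampling coordinates (align_corners=False convention)."""
    scale = src / dst
    return (np.arange(dst) + 0.5) * scale - 0.5


def resize_volume(vol: Volume3D, target_shape: tuple[int, int, int]) -> Volume3D:
    """Trilinear resampling of intensities to `target_shape` (edges clamped)."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target_shape):
        raise ValueError(f"target shape must be >=1 per axis, got {target_shape}")
    if target_shape == vol.shape:
        return Volume3D(vol.intensities.copy(), vol.spacing)
    grids = np.meshgrid(
        *[_resample_coords(s, t) for s, t in zip(vol.shape, target_shape)], indexing="ij"
    )
    out = ndimage.map_coordinates(
        vol.intensities, np.stack(grids), order=1, mode="nearest"
    ).astype(np.float32)
    new_spacing = tuple(
        sp * s / t for sp, s, t in zip(vol.spacing, vol.shape, target_shape)
    )
    return Volume3D(out, new_spacing)


def resize_mask(mask: LabelMask, target_shape: tuple[int, int, int]) -> LabelMask:
    """Nearest-neighbour resampling; preserves label integrality."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target_shape):
        raise ValueError(f"target shape must be >=1 per axis, got {target_shape}")
    if target_shape == mask.shape:
        return LabelMask(mask.labels.copy(), mask.num_classes, mask.spacing)
    grids = np.meshgrid(
        *[_resample_coords(s, t) for s, t in zip(mask.shape, target_shape)], indexing="ij"
    )
    out = ndimage.map_coordinates(mask.labels, np.stack(grids), order=0, mode="nearest")
    new_spacing = tuple(
        sp * s / t for sp, s, t in zip(mask.spacing, mask.shape, target_shape)
    )
    return LabelMask(out, mask.num_classes, new_spacing)


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour label downsampling by an integer factor (strided pick)."""
    f = int(factor)
    off = f // 2
    return np.ascontiguousarray(labels[off::f, off::f, off::f])
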