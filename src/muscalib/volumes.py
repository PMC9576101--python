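"""Voxel-grid containers and NIfTI I/O.

Thin wrappers around numpy arrays with spacing/affine metadata; nibabel does
the file work.  Masks are integer label volumes on the same grid as the image
(no resampling is performed here — inputs must be pre-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["HUVolume", "DensityVolume", "load_hu_volume", "load_label_mask", "roi_statistics"]


def _check_spacing(spacing) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return spacing


@dataclass
class HUVolume:
    """A CT volume in Hounsfield units with grid metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing[: self.voxels.ndim])
        nib.save(img, str(path))


@dataclass
class DensityVolume:
    """A calibrated density volume (g/cm^3 water-equivalent unless noted)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    units: str = "g/cm^3"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing[: self.voxels.ndim])
        nib.save(img, str(path))


def load_hu_volume(path: str | Path) -> HUVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return HUVolume(data, spacing=spacing, affine=np.asarray(img.affine))


def load_label_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels, atol=1e-3):
        raise ValueError(f"mask {path} contains non-integer labels")
    return labels


def roi_statistics(
    image: HUVolume | np.ndarray,
    mask: np.ndarray,
    label: int,
    aggregate: str = "mean",
) -> tuple[float, float, int]:
    """(centre, SD, n_voxels) of image values under ``mask == label``.

    ``aggregate`` is "mean" (default, conventional QCT practice) or "median".
    """
    voxels = image.voxels if isinstance(image, HUVolume) else np.asarray(image)
    if voxels.shape != mask.shape:
        raise ValueError(f"image shape {voxels.shape} != mask shape {mask.shape}")
    values = voxels[mask == label]
    if values.size == 0:
        raise ValueError(f"label {label} absent from mask")
    if aggregate == "mean":
        centre = float(values.mean())
    elif aggregate == "median":
        centre = float(np.median(values))
    else:
        raise ValueError(f"unknown aggregate '{aggregate}' (use 'mean' or 'median')")
    return centre, float(values.std(ddof=1)) if values.size > 1 else 0.0, int(values.size)
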