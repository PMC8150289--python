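"""NIfTI I/O and the in-memory containers for SUV volumes and lesion masks.

Axis convention: arrays are indexed (x, y, z) with z the transaxial stack
direction; voxel spacing is millimetres per axis. Masks are stored on disk as
unsigned 8-bit NIfTI aligned to their volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SuvVolume",
    "LesionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass
class SuvVolume:
    """A 3D grid of standardized uptake values with isotropic or anisotropic spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LesionMask:
    """A binary lesion mask aligned to a :class:`SuvVolume`.

    ``provenance`` records whether the mask is the original segmentation or a
    morphological perturbation of it; ``achieved_change_pct`` is the realised
    percentage volume change relative to the original mask.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = "original"
    achieved_change_pct: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        if not self.values.any():
            raise ValueError("mask must contain at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.provenance not in ("original", "eroded", "dilated"):
            raise ValueError(f"unknown mask provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, volume: SuvVolume) -> None:
        if self.values.shape != volume.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match volume shape {volume.values.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match volume spacing {volume.spacing}"
            )


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(volume: SuvVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> SuvVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SuvVolume(np.asarray(img.dataobj, dtype=float), spacing)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path, volume: SuvVolume | None = None) -> LesionMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = LesionMask(np.asarray(img.dataobj) > 0, spacing)
    if volume is not None:
        mask.check_aligned(volume)
    return mask
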