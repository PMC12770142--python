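"""3D volume and ROI-mask containers plus NIfTI/NRRD round-trip I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class VolumeGrid:
    """A 3D intensity lattice with physical geometry.

    ``intensities`` is indexed (z, y, x); ``spacing_mm`` is the matching
    (z, y, x) voxel spacing.  Intensities are HU-like but unit-agnostic.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 strictly positive values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class RoiMask:
    """Binary segmentation congruent with a :class:`VolumeGrid`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_congruent(self, volume: VolumeGrid) -> None:
        if self.voxels.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match volume shape {volume.shape}"
            )


@dataclass
class LabeledVolume:
    """A nodule volume, its mask, and the malignancy label."""

    volume: VolumeGrid
    mask: RoiMask
    label: str  # "benign" | "malignant"
    nodule_id: str

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")
        self.mask.check_congruent(self.volume)
        if self.mask.n_voxels == 0:
            raise ValueError(f"nodule {self.nodule_id}: empty mask")


def _to_sitk(arr: np.ndarray, spacing_zyx: tuple[float, float, float],
             origin_zyx: tuple[float, float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(spacing_zyx)))  # sitk uses (x, y, z)
    img.SetOrigin(tuple(reversed(origin_zyx)))
    return img


def volume_to_sitk(v: VolumeGrid) -> sitk.Image:
    return _to_sitk(v.intensities, v.spacing_mm, v.origin)


def mask_to_sitk(m: RoiMask) -> sitk.Image:
    return _to_sitk(m.voxels.astype(np.uint8), m.spacing_mm, m.origin)


def volume_from_sitk(img: sitk.Image) -> VolumeGrid:
    return VolumeGrid(
        intensities=sitk.GetArrayFromImage(img).astype(np.float64),
        spacing_mm=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def mask_from_sitk(img: sitk.Image) -> RoiMask:
    return RoiMask(
        voxels=sitk.GetArrayFromImage(img) > 0,
        spacing_mm=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    """Write to NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension."""
    sitk.WriteImage(volume_to_sitk(v), str(path))


def write_mask(m: RoiMask, path: str | Path) -> None:
    sitk.WriteImage(mask_to_sitk(m), str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    return volume_from_sitk(sitk.ReadImage(str(path)))


def read_mask(path: str | Path) -> RoiMask:
    return mask_from_sitk(sitk.ReadImage(str(path)))
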