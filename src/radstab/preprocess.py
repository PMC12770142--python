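"""Intensity rescaling, isotropic resampling and gray-level discretization.

The extraction convention: intensities min-max rescaled to [0, 2048], image
and mask resampled to 1 mm isotropic voxels (B-spline for the image,
nearest-neighbour for the mask), then fixed-width binning with bin edges
anchored at multiples of the bin width from 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volume import (
    RoiMask,
    VolumeGrid,
    mask_from_sitk,
    mask_to_sitk,
    volume_from_sitk,
    volume_to_sitk,
)


class DegenerateRoiError(ValueError):
    """Raised when an ROI is empty or too small for the requested statistic."""


@dataclass(frozen=True)
class PreprocessSpec:
    intensity_range: tuple[float, float] = (0.0, 2048.0)
    bin_width: float = 25.0
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target_spacing_mm must be strictly positive")
        if self.intensity_range[1] <= self.intensity_range[0]:
            raise ValueError("intensity_range must be increasing")


def rescale_intensities(arr: np.ndarray, out_range: tuple[float, float]) -> np.ndarray:
    """Min-max rescale to ``out_range``.

    A zero-range (constant) input maps to the lower bound.
    """
    lo, hi = float(arr.min()), float(arr.max())
    a, b = out_range
    if hi == lo:
        return np.full_like(arr, a, dtype=np.float64)
    return (arr - lo) / (hi - lo) * (b - a) + a


def _resample(img: sitk.Image, target_spacing_xyz: tuple[float, float, float],
              interpolator: int) -> sitk.Image:
    in_spacing = np.array(img.GetSpacing())
    in_size = np.array(img.GetSize())
    out_size = np.maximum(
        np.round(in_size * in_spacing / np.array(target_spacing_xyz)), 1
    ).astype(int)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(s) for s in target_spacing_xyz))
    res.SetSize([int(s) for s in out_size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    res.SetDefaultPixelValue(0)
    return res.Execute(img)


def preprocess(v: VolumeGrid, m: RoiMask,
               spec: PreprocessSpec = PreprocessSpec()) -> tuple[VolumeGrid, RoiMask]:
    """Rescale to the working intensity range and resample to isotropic voxels.

    Image uses B-spline interpolation, mask nearest-neighbour; raises
    :class:`DegenerateRoiError` if the mask empties out under resampling.
    """
    m.check_congruent(v)
    rescaled = VolumeGrid(
        rescale_intensities(v.intensities, spec.intensity_range),
        spacing_mm=v.spacing_mm,
        origin=v.origin,
    )
    target_xyz = tuple(reversed(spec.target_spacing_mm))
    if tuple(v.spacing_mm) == tuple(spec.target_spacing_mm):
        out_v, out_m = rescaled, RoiMask(m.voxels.copy(), m.spacing_mm, m.origin)
    else:
        img = _resample(volume_to_sitk(rescaled), target_xyz, sitk.sitkBSpline)
        msk = _resample(mask_to_sitk(m), target_xyz, sitk.sitkNearestNeighbor)
        out_v, out_m = volume_from_sitk(img), mask_from_sitk(msk)
        # B-spline can overshoot at edges; clamp back to the working range.
        np.clip(out_v.intensities, spec.intensity_range[0], spec.intensity_range[1],
                out=out_v.intensities)
    if out_m.n_voxels == 0:
        raise DegenerateRoiError("ROI empty after resampling")
    return out_v, out_m


def discretize(values: np.ndarray, bin_width: float = 25.0) -> np.ndarray:
    """Fixed-bin-width discretization to integer gray levels starting at 1.

    Bin edges sit at multiples of ``bin_width`` from 0; the occupied bins
    are shifted so the lowest one becomes level 1.  The number of gray
    levels is then ``max(result)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=np.float64)
    raw = np.floor(values / bin_width).astype(np.int64)
    return raw - raw.min() + 1
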