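"""Image filter bank: wavelet sub-bands, Laplacian of Gaussian, algebraic maps.

Each filter produces a derived volume congruent with the input, so the
original ROI mask applies unchanged; intensity features are then recomputed
on each derived volume.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .volume import VolumeGrid


def wavelet_subbands(v: VolumeGrid, wavelet: str = "coif1") -> dict[str, VolumeGrid]:
    """Single-level undecimated 3D wavelet decomposition, 8 sub-bands.

    Sub-bands are named ``LLL``..``HHH`` by (z, y, x) low/high-pass choice.
    The stationary transform keeps the grid size, so masks stay congruent;
    odd axes are edge-padded to even length and cropped back.
    """
    arr = v.intensities
    pad = [(0, s % 2) for s in arr.shape]
    padded = np.pad(arr, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out: dict[str, VolumeGrid] = {}
    crop = tuple(slice(0, s) for s in arr.shape)
    for key, sub in coeffs.items():
        name = key.replace("a", "L").replace("d", "H")
        out[f"wavelet-{name}"] = VolumeGrid(sub[crop], spacing_mm=v.spacing_mm,
                                            origin=v.origin)
    return out


def log_filter(v: VolumeGrid, sigma_mm: float) -> VolumeGrid:
    """Scale-normalised Laplacian of Gaussian at physical width sigma (mm)."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    sigma_vox = [sigma_mm / s for s in v.spacing_mm]
    raw = ndimage.gaussian_laplace(v.intensities, sigma=sigma_vox, mode="nearest")
    # The discrete derivative-of-Gaussian kernel has a tiny nonzero DC gain;
    # subtract it so a constant volume maps exactly to zero.
    probe = np.ones([2 * int(np.ceil(4 * s)) + 3 for s in sigma_vox])
    dc = ndimage.gaussian_laplace(probe, sigma=sigma_vox, mode="nearest")[
        tuple(s // 2 for s in probe.shape)]
    resp = sigma_mm**2 * (raw - dc * v.intensities)
    return VolumeGrid(resp, spacing_mm=v.spacing_mm, origin=v.origin)


def _abs_max(arr: np.ndarray) -> float:
    return float(np.abs(arr).max())


def square_filter(v: VolumeGrid) -> VolumeGrid:
    """(c x)^2 with c = 1/sqrt(max|x|): squares intensities, preserving range."""
    m = _abs_max(v.intensities)
    out = np.zeros_like(v.intensities) if m == 0 else (v.intensities / np.sqrt(m)) ** 2 * np.sign(v.intensities)
    return VolumeGrid(out, spacing_mm=v.spacing_mm, origin=v.origin)


def squareroot_filter(v: VolumeGrid) -> VolumeGrid:
    """sqrt(c x) for x >= 0, -sqrt(-c x) for x < 0, c = max|x| (range-preserving)."""
    m = _abs_max(v.intensities)
    x = v.intensities
    out = np.sign(x) * np.sqrt(m * np.abs(x))
    return VolumeGrid(out, spacing_mm=v.spacing_mm, origin=v.origin)


def exponential_filter(v: VolumeGrid) -> VolumeGrid:
    """exp(c x) with c = log(max|x|) / max|x|, mapping the maximum to itself."""
    m = _abs_max(v.intensities)
    if m == 0:
        out = np.ones_like(v.intensities)
    else:
        out = np.exp(np.log(m) / m * v.intensities)
    return VolumeGrid(out, spacing_mm=v.spacing_mm, origin=v.origin)


def filter_images(v: VolumeGrid,
                  image_types: tuple[str, ...] = ("wavelet", "log", "square",
                                                  "squareroot", "exponential"),
                  log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0),
                  wavelet: str = "coif1") -> dict[str, VolumeGrid]:
    """All configured derived volumes, keyed by image-type name."""
    out: dict[str, VolumeGrid] = {}
    if "wavelet" in image_types:
        out.update(wavelet_subbands(v, wavelet=wavelet))
    if "log" in image_types:
        for s in log_sigmas_mm:
            tag = f"{s:.1f}".replace(".", "-")
            out[f"log-sigma-{tag}-mm-3D"] = log_filter(v, s)
    if "square" in image_types:
        out["square"] = square_filter(v)
    if "squareroot" in image_types:
        out["squareroot"] = squareroot_filter(v)
    if "exponential" in image_types:
        out["exponential"] = exponential_filter(v)
    return out
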