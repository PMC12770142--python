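"""Reduced IBSI-style radiomic feature extraction.

Families implemented: 18 first-order statistics, 14 shape descriptors, and
24 gray-level co-occurrence (GLCM) statistics; the intensity families are
recomputed on each filtered image of the configured bank (8 wavelet
sub-bands, 3 Laplacian-of-Gaussian scales, square / square-root /
exponential), giving 14 + 42 x 15 = 644 features with the defaults.
Shape is computed once, on the original-geometry mask.

Degenerate statistics (correlation of a single gray level, sphericity of a
single voxel) are emitted as NaN sentinels, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .filters import filter_images
from .preprocess import DegenerateRoiError, PreprocessSpec, discretize, preprocess
from .volume import RoiMask, VolumeGrid

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "TotalEnergy", "Entropy", "Uniformity",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "10Percentile", "90Percentile", "InterquartileRange",
)

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "JointVariance", "MCC", "MaximumProbability", "SumAverage", "SumEntropy",
)

#: The 13 unique 3D voxel offsets at Chebyshev distance 1 (half of the 26
#: neighbours; the co-occurrence matrix is symmetrised so the other half is
#: implied).
OFFSETS_3D = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


def first_order_features(v: VolumeGrid, m: RoiMask,
                         bin_width: float = 25.0) -> dict[str, float]:
    """The 18 first-order intensity statistics over masked voxels.

    Entropy and uniformity use the fixed-bin-width discretized histogram;
    every other statistic uses the continuous intensities.
    """
    m.check_congruent(v)
    x = v.intensities[m.voxels]
    n = x.size
    if n < 2:
        raise DegenerateRoiError(
            "first-order dispersion statistics require at least 2 voxels"
        )
    levels = discretize(x, bin_width)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n

    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    m3 = np.mean((x - mean) ** 3)
    m4 = np.mean((x - mean) ** 4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    voxel_vol = v.voxel_volume_mm3

    return {
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(var),
        "Skewness": float(m3 / sd**3) if sd > 0 else np.nan,
        "Kurtosis": float(m4 / var**2) if var > 0 else np.nan,
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_vol * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Uniformity": float(np.sum(p**2)),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
    }


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull prefilter when the
    point cloud is large enough for qhull."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 10 and pts.shape[1] >= 2:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) clouds: brute force
    return float(pdist(pts).max())


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def _max_2d_diameter(bcoords_mm: np.ndarray, bindex: np.ndarray, fixed_axis: int) -> float:
    plane_axes = [a for a in range(3) if a != fixed_axis]
    best = 0.0
    for val in np.unique(bindex[:, fixed_axis]):
        pts = bcoords_mm[bindex[:, fixed_axis] == val][:, plane_axes]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(m: RoiMask, spacing_mm: tuple[float, float, float] | None = None
                   ) -> dict[str, float]:
    """The 14 3D shape descriptors of a binary ROI.

    Mesh volume/surface come from a marching-cubes surface at level 0.5;
    maximum diameters use boundary-voxel centres; axis lengths come from the
    eigenvalues of the physical-coordinate covariance (population moments).
    A single-voxel mask yields zero diameters and NaN sentinels for
    sphericity, elongation and flatness.
    """
    spacing = np.asarray(spacing_mm if spacing_mm is not None else m.spacing_mm,
                         dtype=float)
    mask = m.voxels
    n = int(mask.sum())
    if n == 0:
        raise DegenerateRoiError("shape features require a nonempty mask")

    voxel_volume = float(n * spacing.prod())

    # Slight smoothing of the binary lattice before surface extraction
    # suppresses the staircase artifact that inflates surface area (and
    # deflates sphericity) on digitized round objects.
    from scipy import ndimage
    padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float64), sigma=0.6,
                                     mode="nearest")
    if padded.max() <= 0.5:  # tiny masks smooth away; use the raw lattice
        padded = np.pad(mask, 2).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                      np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    if n == 1:
        return {
            "MeshVolume": mesh_volume, "VoxelVolume": voxel_volume,
            "SurfaceArea": surface_area,
            "SurfaceVolumeRatio": surface_area / mesh_volume,
            "Sphericity": np.nan, "Maximum3DDiameter": 0.0,
            "Maximum2DDiameterSlice": 0.0, "Maximum2DDiameterColumn": 0.0,
            "Maximum2DDiameterRow": 0.0, "MajorAxisLength": 0.0,
            "MinorAxisLength": 0.0, "LeastAxisLength": 0.0,
            "Elongation": np.nan, "Flatness": np.nan,
        }

    sphericity = float((36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area)

    bindex = _boundary_voxels(mask)
    bcoords = bindex * spacing
    max3d = _max_pairwise(bcoords)
    # Slice: in-plane (axial) distances; Column: slice-row plane; Row:
    # slice-column plane — each maximised over its stack of planes.
    max2d_slice = _max_2d_diameter(bcoords, bindex, fixed_axis=0)
    max2d_col = _max_2d_diameter(bcoords, bindex, fixed_axis=2)
    max2d_row = _max_2d_diameter(bcoords, bindex, fixed_axis=1)

    coords = np.argwhere(mask) * spacing
    cov = np.cov(coords, rowvar=False, ddof=0)
    eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    major, minor, least = (float(4.0 * np.sqrt(e)) for e in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_col,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


def cooccurrence_matrices(levels: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """Symmetric gray-level co-occurrence counts for the 13 3D offsets.

    ``levels`` holds gray levels 1..Ng inside the mask (values outside are
    ignored).  Returns one Ng x Ng count matrix per offset; offsets with no
    valid pair yield an all-zero matrix.
    """
    ng = int(levels[mask].max())
    mats = []
    for dz, dy, dx in OFFSETS_3D:
        src = [slice(max(0, -d), levels.shape[a] - max(0, d))
               for a, d in enumerate((dz, dy, dx))]
        dst = [slice(max(0, d), levels.shape[a] + min(0, d))
               for a, d in enumerate((dz, dy, dx))]
        ok = mask[tuple(src)] & mask[tuple(dst)]
        a = levels[tuple(src)][ok] - 1
        b = levels[tuple(dst)][ok] - 1
        mat = np.zeros((ng, ng))
        np.add.at(mat, (a, b), 1.0)
        mats.append(mat + mat.T)  # symmetrise: count both directions
    return mats


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        pxy = np.outer(px, py)
        lg = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * lg).sum())
    hxy2 = float(-(pxy * lg).sum())
    hx, hy = ent(px), ent(py)

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    diff_avg = float((k_diff * p_diff).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())

    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.einsum("ik,jk->ij", p / np.where(px[:, None] > 0, px[:, None], 1.0),
                          np.where(py > 0, p / py, 0.0))
        eigs = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eigs[-2]))) if len(eigs) > 1 else 1.0
    else:
        mcc = 1.0

    correlation = (
        float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y))
        if sd_x > 0 and sd_y > 0 else np.nan
    )

    off_diag = ii != jj
    with np.errstate(divide="ignore"):
        inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if ng > 1 else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "JointVariance": float(((ii - mu_x) ** 2 * p).sum()),
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
    }


def glcm_features(v: VolumeGrid, m: RoiMask, bin_width: float = 25.0) -> dict[str, float]:
    """The 24 GLCM statistics, averaged over the 13 unique 3D directions."""
    m.check_congruent(v)
    if m.n_voxels == 0:
        raise DegenerateRoiError("GLCM features require a nonempty mask")
    levels = np.zeros(v.shape, dtype=np.int64)
    levels[m.voxels] = discretize(v.intensities[m.voxels], bin_width)
    mats = cooccurrence_matrices(levels, m.voxels)
    per_dir = []
    for mat in mats:
        total = mat.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_stats(mat / total))
    if not per_dir:
        raise DegenerateRoiError("no co-occurring voxel pairs in ROI")
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionConfig:
    """Which image types and families to extract.

    ``image_types`` lists derived-image groups beyond ``original``:
    ``wavelet`` (8 sub-bands), ``log`` (one volume per sigma), ``square``,
    ``squareroot``, ``exponential``.
    """

    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    image_types: tuple[str, ...] = ("wavelet", "log", "square", "squareroot",
                                    "exponential")
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "coif1"

    def expected_feature_count(self) -> int:
        n_images = 1
        if "wavelet" in self.image_types:
            n_images += 8
        if "log" in self.image_types:
            n_images += len(self.log_sigmas_mm)
        for t in ("square", "squareroot", "exponential"):
            if t in self.image_types:
                n_images += 1
        return len(SHAPE_NAMES) + n_images * (len(FIRST_ORDER_NAMES) + len(GLCM_NAMES))


def extract_all(v: VolumeGrid, m: RoiMask,
                config: ExtractionConfig = ExtractionConfig()) -> dict[str, float]:
    """Extract the full configured feature vector for one nodule.

    Returns an ordered ``{feature_name: value}`` mapping named
    ``<imagetype>_<class>_<feature>``; shape features are computed once on
    the preprocessed original mask, intensity families on the original and
    every derived image.
    """
    pv, pm = preprocess(v, m, config.preprocess)
    bw = config.preprocess.bin_width

    out: dict[str, float] = {}
    for name, val in shape_features(pm).items():
        out[f"original_shape_{name}"] = val

    images = {"original": pv}
    images.update(filter_images(pv, image_types=config.image_types,
                                log_sigmas_mm=config.log_sigmas_mm,
                                wavelet=config.wavelet))
    for img_name, img in images.items():
        for name, val in first_order_features(img, pm, bin_width=bw).items():
            out[f"{img_name}_firstorder_{name}"] = val
        for name, val in glcm_features(img, pm, bin_width=bw).items():
            out[f"{img_name}_glcm_{name}"] = val
    return out
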