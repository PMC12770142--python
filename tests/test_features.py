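import numpy as np
import pytest

from radstab.features import (
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    OFFSETS_3D,
    SHAPE_NAMES,
    ExtractionConfig,
    extract_all,
    first_order_features,
    glcm_features,
    shape_features,
)
from radstab.filters import (
    exponential_filter,
    filter_images,
    log_filter,
    square_filter,
    squareroot_filter,
    wavelet_subbands,
)
from radstab.preprocess import DegenerateRoiError, discretize
from radstab.volume import RoiMask, VolumeGrid


# ---------------------------------------------------------------------------
# independent naive oracles
# ---------------------------------------------------------------------------

def naive_first_order(x, voxel_volume=1.0, bin_width=25.0):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = var**0.5
    lv = discretize(x, bin_width)
    p = np.bincount(lv)[1:]
    p = p[p > 0] / n
    p10, p25, p50, p75, p90 = (np.percentile(x, q) for q in (10, 25, 50, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    return {
        "Mean": mean, "Median": p50, "Minimum": x[0], "Maximum": x[-1],
        "Range": x[-1] - x[0], "Variance": var,
        "Skewness": sum((v - mean) ** 3 for v in x) / n / sd**3,
        "Kurtosis": sum((v - mean) ** 4 for v in x) / n / var**2,
        "Energy": sum(v**2 for v in x),
        "TotalEnergy": voxel_volume * sum(v**2 for v in x),
        "Entropy": -sum(q * np.log2(q) for q in p),
        "Uniformity": sum(q**2 for q in p),
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": (sum(v**2 for v in x) / n) ** 0.5,
        "10Percentile": p10, "90Percentile": p90, "InterquartileRange": p75 - p25,
    }


def naive_glcm(levels, mask):
    """Brute-force pair enumeration + direct-formula GLCM statistics."""
    ng = int(levels[mask].max())
    out = []
    shape = levels.shape
    for off in OFFSETS_3D:
        mat = np.zeros((ng, ng))
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x]:
                        continue
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                            and mask[z2, y2, x2]:
                        a, b = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                        mat[a, b] += 1
                        mat[b, a] += 1
        if mat.sum() > 0:
            out.append(mat / mat.sum())
    return out


def naive_glcm_stats(p):
    ng = p.shape[0]
    idx = range(1, ng + 1)
    px = [sum(p[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1, j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    sd_x = (sum((i - mu_x) ** 2 * px[i - 1] for i in idx)) ** 0.5
    sd_y = (sum((j - mu_y) ** 2 * py[j - 1] for j in idx)) ** 0.5
    psum = {k: sum(p[i - 1, j - 1] for i in idx for j in idx if i + j == k)
            for k in range(2, 2 * ng + 1)}
    pdiff = {k: sum(p[i - 1, j - 1] for i in idx for j in idx if abs(i - j) == k)
             for k in range(0, ng)}
    ent = lambda vals: -sum(v * np.log2(v) for v in vals if v > 0)
    hxy = ent(p.ravel())
    hxy1 = -sum(p[i - 1, j - 1] * np.log2(px[i - 1] * py[j - 1])
                for i in idx for j in idx
                if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = -sum(px[i - 1] * py[j - 1] * np.log2(px[i - 1] * py[j - 1])
                for i in idx for j in idx if px[i - 1] * py[j - 1] > 0)
    hx, hy = ent(px), ent(py)
    da = sum(k * v for k, v in pdiff.items())
    q = np.zeros((ng, ng))
    for i in idx:
        for j in idx:
            q[i - 1, j - 1] = sum(
                p[i - 1, k - 1] * p[j - 1, k - 1] / (px[i - 1] * py[k - 1])
                for k in idx if px[i - 1] > 0 and py[k - 1] > 0)
    eigs = sorted(np.real(np.linalg.eigvals(q)))
    return {
        "Autocorrelation": sum(i * j * p[i - 1, j - 1] for i in idx for j in idx),
        "ClusterProminence": sum((i + j - mu_x - mu_y) ** 4 * p[i - 1, j - 1]
                                 for i in idx for j in idx),
        "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * p[i - 1, j - 1]
                            for i in idx for j in idx),
        "ClusterTendency": sum((i + j - mu_x - mu_y) ** 2 * p[i - 1, j - 1]
                               for i in idx for j in idx),
        "Contrast": sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx),
        "Correlation": sum((i - mu_x) * (j - mu_y) * p[i - 1, j - 1]
                           for i in idx for j in idx) / (sd_x * sd_y),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(p[i - 1, j - 1] / (1 + abs(i - j)) for i in idx for j in idx),
        "Idm": sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx),
        "Idmn": sum(p[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2)
                    for i in idx for j in idx),
        "Idn": sum(p[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in idx for j in idx),
        "Imc1": (hxy - hxy1) / max(hx, hy),
        "Imc2": (max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))) ** 0.5,
        "InverseVariance": sum(p[i - 1, j - 1] / (i - j) ** 2
                               for i in idx for j in idx if i != j),
        "JointAverage": mu_x,
        "JointEnergy": sum(v**2 for v in p.ravel()),
        "JointEntropy": hxy,
        "JointVariance": sum((i - mu_x) ** 2 * p[i - 1, j - 1]
                             for i in idx for j in idx),
        "MCC": max(0.0, eigs[-2]) ** 0.5,
        "MaximumProbability": p.max(),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": ent(psum.values()),
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_region(self):
        v = VolumeGrid(np.full((3, 3, 3), 42.0), (1, 1, 1))
        fo = first_order_features(v, RoiMask(np.ones((3, 3, 3), bool)))
        for key in ("Mean", "Median", "Minimum", "Maximum"):
            assert fo[key] == 42.0
        assert fo["Variance"] == 0.0
        assert fo["Range"] == 0.0
        assert np.isnan(fo["Skewness"])  # sentinel, not silent zero

    def test_uniform_bins_entropy(self):
        vals = np.repeat([10.0, 35.0, 60.0, 85.0, 110.0, 135.0, 160.0, 185.0], 8)
        v = VolumeGrid(vals.reshape(4, 4, 4), (1, 1, 1))
        fo = first_order_features(v, RoiMask(np.ones((4, 4, 4), bool)))
        assert fo["Entropy"] == pytest.approx(3.0, abs=1e-12)  # log2(8)
        assert fo["Uniformity"] == pytest.approx(1 / 8, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        arr = rng.uniform(0, 2048, size=(5, 5, 4))
        v = VolumeGrid(arr, (1.0, 1.2, 0.8))
        fo = first_order_features(v, RoiMask(np.ones((5, 5, 4), bool), (1.0, 1.2, 0.8)))
        oracle = naive_first_order(arr.ravel(), voxel_volume=1.0 * 1.2 * 0.8)
        for name in FIRST_ORDER_NAMES:
            assert fo[name] == pytest.approx(oracle[name], abs=1e-10, rel=1e-10), name

    def test_single_voxel_raises(self):
        v = VolumeGrid(np.zeros((1, 1, 1)), (1, 1, 1))
        with pytest.raises(DegenerateRoiError):
            first_order_features(v, RoiMask(np.ones((1, 1, 1), bool)))

    def test_mean_affine_equivariant(self, random_roi):
        v, m = random_roi
        fo = first_order_features(v, m)
        v2 = VolumeGrid(3.0 * v.intensities + 7.0, v.spacing_mm)
        fo2 = first_order_features(v2, m)
        assert fo2["Mean"] == pytest.approx(3.0 * fo["Mean"] + 7.0, rel=1e-12)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

class TestShape:
    def test_cube_volume_and_diameter(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[2:5, 2:5, 2:5] = True
        sf = shape_features(RoiMask(mask, (1, 1, 1)))
        assert sf["VoxelVolume"] == pytest.approx(27.0)
        # centre-to-centre convention: corner voxel centres are 2*sqrt(3) apart
        assert sf["Maximum3DDiameter"] == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_digitized_sphere(self):
        zz, yy, xx = np.meshgrid(*[np.arange(16) - 7.5] * 3, indexing="ij")
        sph = (zz**2 + yy**2 + xx**2) <= 5.0**2
        sf = shape_features(RoiMask(sph, (1, 1, 1)))
        assert 0.95 <= sf["Sphericity"] <= 1.0
        assert sf["Maximum3DDiameter"] == pytest.approx(10.0, abs=1.0)
        assert sf["MeshVolume"] == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)
        assert sf["Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_single_voxel_sentinels(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        sf = shape_features(RoiMask(mask, (1, 1, 1)))
        assert sf["Maximum3DDiameter"] == 0.0
        assert np.isnan(sf["Sphericity"])
        assert sf["VoxelVolume"] == 1.0

    def test_intensity_independent(self, random_roi):
        _, m = random_roi
        assert shape_features(m) == shape_features(m)  # depends on mask only

    def test_spacing_scales_features(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[2:5, 2:5, 2:5] = True
        a = shape_features(RoiMask(mask, (1, 1, 1)))
        b = shape_features(RoiMask(mask, (2, 2, 2)))
        assert b["VoxelVolume"] == pytest.approx(8 * a["VoxelVolume"])
        assert b["Maximum3DDiameter"] == pytest.approx(2 * a["Maximum3DDiameter"])


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_constant_region(self):
        v = VolumeGrid(np.full((4, 4, 4), 99.0), (1, 1, 1))
        g = glcm_features(v, RoiMask(np.ones((4, 4, 4), bool)))
        assert g["Contrast"] == 0.0
        assert g["JointEnergy"] == 1.0
        assert np.isnan(g["Correlation"])  # sentinel for single gray level

    def test_stripe_pattern_contrast_by_hand(self):
        # two-level stripes along x: 0,25,0,25 -> along-x pairs always differ
        arr = np.zeros((1, 1, 6))
        arr[0, 0, 1::2] = 25.0
        mask = np.ones((1, 1, 6), bool)
        v = VolumeGrid(arr, (1, 1, 1))
        g = glcm_features(v, RoiMask(mask))
        # only the x-offset produces pairs: all 10 (symmetric) pairs are (1,2)
        # or (2,1), each |i-j| = 1 -> contrast 1
        assert g["Contrast"] == pytest.approx(1.0, abs=1e-12)
        assert g["MaximumProbability"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_enumeration(self, rng):
        arr = (rng.integers(0, 8, size=(5, 5, 5)) * 25).astype(float)
        zz, yy, xx = np.meshgrid(*[np.arange(5) - 2] * 3, indexing="ij")
        mask = (zz**2 + yy**2 + xx**2) <= 2.2**2
        v = VolumeGrid(arr, (1, 1, 1))
        g = glcm_features(v, RoiMask(mask))
        levels = np.zeros_like(arr, dtype=np.int64)
        levels[mask] = discretize(arr[mask])
        mats = naive_glcm(levels, mask)
        oracle = {name: np.mean([naive_glcm_stats(p)[name] for p in mats])
                  for name in GLCM_NAMES}
        for name in GLCM_NAMES:
            assert g[name] == pytest.approx(oracle[name], abs=1e-10, rel=1e-10), name


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_constant_volume_wavelet_details_zero(self):
        v = VolumeGrid(np.full((8, 8, 8), 50.0), (1, 1, 1))
        bands = wavelet_subbands(v)
        assert len(bands) == 8
        for name, band in bands.items():
            if "H" in name:
                assert np.allclose(band.intensities, 0.0, atol=1e-9), name
            else:
                assert np.ptp(band.intensities) < 1e-9  # constant approximation

    def test_constant_volume_log_zero(self):
        v = VolumeGrid(np.full((10, 10, 10), 77.0), (1, 1, 1))
        out = log_filter(v, 2.0)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_log_sigma_must_be_positive(self):
        v = VolumeGrid(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            log_filter(v, 0.0)

    def test_squareroot_inverse_recovers_input(self, rng):
        arr = rng.uniform(0, 2048, size=(5, 5, 5))
        v = VolumeGrid(arr, (1, 1, 1))
        f = squareroot_filter(v)
        c = np.abs(arr).max()
        recovered = f.intensities**2 / c
        assert np.allclose(recovered, arr, atol=1e-8)

    def test_square_and_exponential_preserve_range(self, rng):
        arr = rng.uniform(0, 2048, size=(4, 4, 4))
        arr.flat[0] = 2048.0
        v = VolumeGrid(arr, (1, 1, 1))
        assert square_filter(v).intensities.max() == pytest.approx(2048.0)
        assert exponential_filter(v).intensities.max() == pytest.approx(2048.0)

    def test_filter_images_naming(self):
        v = VolumeGrid(np.random.default_rng(0).normal(size=(8, 8, 8)), (1, 1, 1))
        out = filter_images(v)
        wavelets = [k for k in out if k.startswith("wavelet-")]
        logs = [k for k in out if k.startswith("log-sigma-")]
        assert len(wavelets) == 8 and len(logs) == 3
        assert {"square", "squareroot", "exponential"} <= set(out)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def extracted():
    rng = np.random.default_rng(5)
    shape = (16, 20, 20)
    zz, yy, xx = np.meshgrid(np.arange(16) - 7.5, np.arange(20) - 9.5,
                             np.arange(20) - 9.5, indexing="ij")
    mask = (zz**2 + yy**2 + xx**2) <= 5.5**2
    v = VolumeGrid(rng.normal(-200, 150, shape), (1, 1, 1))
    m = RoiMask(mask, (1, 1, 1))
    return v, m, extract_all(v, m)


class TestExtractAll:
    def test_default_config_column_count(self, extracted):
        _, _, feats = extracted
        assert len(feats) == 644
        assert len(feats) == ExtractionConfig().expected_feature_count()

    def test_deterministic(self, extracted):
        v, m, feats = extracted
        assert extract_all(v, m) == feats

    def test_prefix_partition_counts(self, extracted):
        _, _, feats = extracted
        by_prefix = {}
        for k in feats:
            by_prefix.setdefault(k.split("_")[0], []).append(k)
        assert len(by_prefix["original"]) == 14 + 18 + 24
        for prefix, keys in by_prefix.items():
            if prefix != "original":
                assert len(keys) == 18 + 24, prefix

    def test_composition_consistency(self, extracted):
        v, m, feats = extracted
        from radstab.preprocess import preprocess
        pv, pm = preprocess(v, m)
        fo = first_order_features(pv, pm)
        sf = shape_features(pm)
        assert feats["original_firstorder_Mean"] == fo["Mean"]
        assert feats["original_shape_MeshVolume"] == sf["MeshVolume"]

    def test_layout_invariance(self, extracted):
        # storage order must not matter: extract from a Fortran-ordered copy
        v, m, feats = extracted
        vf = VolumeGrid(np.asfortranarray(v.intensities), v.spacing_mm)
        mf = RoiMask(np.asfortranarray(m.voxels), m.spacing_mm)
        feats_f = extract_all(vf, mf)
        for k, val in feats.items():
            assert feats_f[k] == pytest.approx(val, rel=1e-12, abs=1e-12), k
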