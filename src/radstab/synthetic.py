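"""Synthetic phantom cohorts and feature panels with known ground truth.

Two complementary generators stand in for unreleased patient data:

* :func:`make_phantom_cohort` builds 3D lung-window-like nodule phantoms at
  the reference reconstruction geometry, and :func:`apply_setting` degrades
  them the way each acquisition setting would (slab averaging for thicker
  slices, in-plane resampling for a coarser matrix, blur/sharpen for the
  kernel family, 12-bit quantisation for PACS export).
* :func:`simulate_feature_panel` skips imaging entirely and draws per-setting
  feature tables from a two-way (subject x setting) variance-component model
  calibrated so each feature's population ICC(A,1) equals a requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .settings import (
    REFERENCE_SETTING_ID,
    SETTINGS,
    SETTINGS_BY_ID,
    AcquisitionSetting,
)
from .volume import LabeledVolume, RoiMask, VolumeGrid

# Reference reconstruction geometry: 1 mm slices, fine in-plane grid
# (0.5 mm, emulating a 1024 matrix over a nodule-sized field of view).
REF_SPACING_MM = (1.0, 0.5, 0.5)
REF_SHAPE = (45, 80, 80)

#: One-parameter blur/sharpen family standing in for the proprietary
#: reconstruction kernels.  B_SHARP_C is the reference (identity); sigma is
#: the in-plane Gaussian width in mm, amount the unsharp-mask gain.
KERNEL_OPERATORS: Mapping[str, dict] = {
    "B_SHARP_C": {"mode": "identity"},
    "B_SHARP_A": {"mode": "blur", "sigma_mm": 0.3},
    "B_SOFT_C": {"mode": "blur", "sigma_mm": 0.6},
    "B_SOFT_F": {"mode": "blur", "sigma_mm": 1.0},
    "B_VSOFT_A": {"mode": "blur", "sigma_mm": 1.5},
    "B_VSHARP_D": {"mode": "sharpen", "sigma_mm": 1.0, "amount": 1.0},
}


@dataclass
class PhantomSpec:
    """Parameters of a phantom nodule cohort.

    Diameters are equivalent-sphere diameters drawn from a normal
    distribution truncated to ``diameter_range_mm``; the defaults reproduce
    the size distribution of a routine clinical nodule cohort
    (9.31 +/- 4.90 mm, 5-30 mm inclusion window).
    """

    n_nodules: int
    diameter_mean_mm: float = 9.31
    diameter_sd_mm: float = 4.90
    diameter_range_mm: tuple[float, float] = (5.0, 30.0)
    background_level: float = -800.0
    background_noise_sd: float = 50.0
    nodule_level: float = -50.0
    malignant_fraction: float = 0.5
    malignant_texture_effect: float = 1.0
    shape_irregularity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_mm
        if not (0 < lo < hi):
            raise ValueError("diameter_range_mm must satisfy 0 < min < max")
        if not 0 <= self.malignant_fraction <= 1:
            raise ValueError("malignant_fraction must be in [0, 1]")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")
        if self.diameter_sd_mm <= 0:
            raise ValueError("diameter_sd_mm must be > 0")
        if not 0 <= self.shape_irregularity <= 1:
            raise ValueError("shape_irregularity must be in [0, 1]")


def truncated_diameter_distribution(spec: PhantomSpec) -> stats.rv_continuous:
    """The frozen truncated normal the cohort diameters are drawn from."""
    lo, hi = spec.diameter_range_mm
    a = (lo - spec.diameter_mean_mm) / spec.diameter_sd_mm
    b = (hi - spec.diameter_mean_mm) / spec.diameter_sd_mm
    return stats.truncnorm(a, b, loc=spec.diameter_mean_mm, scale=spec.diameter_sd_mm)


def sample_diameters(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``spec.n_nodules`` equivalent-sphere diameters (mm)."""
    dist = truncated_diameter_distribution(spec)
    return dist.rvs(size=spec.n_nodules, random_state=rng)


def _smooth_noise_field(shape: tuple[int, int, int], sigma_vox: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-sd spatially correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd == 0:
        return f
    return (f - f.mean()) / sd


def _build_nodule(diameter_mm: float, malignant: bool, spec: PhantomSpec,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape = REF_SHAPE
    spacing = np.array(REF_SPACING_MM)
    zc, yc, xc = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) - zc) * spacing[0],
        (np.arange(shape[1]) - yc) * spacing[1],
        (np.arange(shape[2]) - xc) * spacing[2],
        indexing="ij",
    )

    # Mild random anisotropy with unit geometric mean keeps the
    # equivalent-sphere diameter at the drawn value.
    logs = rng.normal(0.0, 0.12, size=3)
    axis_scale = np.exp(logs - logs.mean())
    r = diameter_mm / 2.0
    dist = np.sqrt((zz / axis_scale[0]) ** 2 + (yy / axis_scale[1]) ** 2
                   + (xx / axis_scale[2]) ** 2)

    # Surface irregularity: radius modulated by a smooth zero-mean field.
    if spec.shape_irregularity > 0:
        bump = _smooth_noise_field(shape, sigma_vox=4.0, rng=rng)
        r_eff = r * (1.0 + 0.15 * spec.shape_irregularity * bump)
    else:
        r_eff = np.full(shape, r)
    mask = dist <= r_eff

    noise = rng.normal(0.0, spec.background_noise_sd, size=shape)
    vol = spec.background_level + noise
    vol[mask] = spec.nodule_level + noise[mask] * 0.5
    if malignant and spec.malignant_texture_effect > 0:
        # Intra-nodule heterogeneity: correlated texture scaled in units of
        # the background noise sd.
        tex = _smooth_noise_field(shape, sigma_vox=1.5, rng=rng)
        vol[mask] += (spec.malignant_texture_effect * spec.background_noise_sd
                      * tex[mask])
    # Slight edge softening emulates the finite reconstruction PSF.
    vol = ndimage.gaussian_filter(vol, sigma=0.5, mode="nearest")
    return vol, mask


def make_phantom_cohort(spec: PhantomSpec) -> list[LabeledVolume]:
    """Generate a cohort of labelled phantom nodules at reference geometry.

    Deterministic for a fixed ``spec.seed``: one master seed is fanned out
    into independent per-nodule child streams.
    """
    ss = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    n_mal = int(round(spec.n_nodules * spec.malignant_fraction))
    labels = np.array(["malignant"] * n_mal + ["benign"] * (spec.n_nodules - n_mal))
    label_rng.shuffle(labels)

    diam_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    diameters = sample_diameters(spec, diam_rng)

    cohort: list[LabeledVolume] = []
    for i in range(spec.n_nodules):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2, i)))
        vol, mask = _build_nodule(float(diameters[i]), labels[i] == "malignant", spec, rng)
        cohort.append(
            LabeledVolume(
                volume=VolumeGrid(vol, spacing_mm=REF_SPACING_MM),
                mask=RoiMask(mask, spacing_mm=REF_SPACING_MM),
                label=str(labels[i]),
                nodule_id=f"N{i:04d}",
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Acquisition-setting transforms
# ---------------------------------------------------------------------------

def _apply_kernel(arr: np.ndarray, kernel_id: str, spacing_mm: Sequence[float]) -> np.ndarray:
    op = KERNEL_OPERATORS[kernel_id]
    if op["mode"] == "identity":
        return arr
    sigma_vox = (0.0, op["sigma_mm"] / spacing_mm[1], op["sigma_mm"] / spacing_mm[2])
    blurred = ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="nearest")
    if op["mode"] == "blur":
        return blurred
    return arr + op["amount"] * (arr - blurred)  # unsharp masking


def _slab_average(arr: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k-slab mean along axis 0; trailing partial slab
    averaged over the remaining slices."""
    nz = arr.shape[0]
    n_full, rem = divmod(nz, k)
    slabs = []
    for j in range(n_full):
        slabs.append(arr[j * k:(j + 1) * k].mean(axis=0))
    if rem:
        slabs.append(arr[n_full * k:].mean(axis=0))
    return np.stack(slabs, axis=0)


def _slab_mask(mask: np.ndarray, k: int) -> np.ndarray:
    """Nearest-neighbour mask transfer: each slab takes its centre slice."""
    nz = mask.shape[0]
    n_out = -(-nz // k)
    idx = np.minimum(np.arange(n_out) * k + k // 2, nz - 1)
    return mask[idx]


def _downsample_inplane(arr: np.ndarray, order: int) -> np.ndarray:
    return ndimage.zoom(arr, (1.0, 0.5, 0.5), order=order, mode="nearest",
                        grid_mode=True)


def _quantize_12bit(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return arr.copy()
    q = np.round((arr - lo) / (hi - lo) * 4095.0)
    return q / 4095.0 * (hi - lo) + lo


def apply_setting(v: LabeledVolume, s: AcquisitionSetting | str) -> LabeledVolume:
    """Reconstruct a reference-geometry nodule under acquisition setting ``s``.

    The reference setting S2 is the identity.  Operators are applied in
    reconstruction order: kernel, slice thickness, matrix, transmission.
    Deterministic: no randomness is involved.
    """
    if isinstance(s, str):
        s = SETTINGS_BY_ID[s]
    arr = v.volume.intensities
    mask = v.mask.voxels
    spacing = list(v.volume.spacing_mm)

    arr = _apply_kernel(arr, s.kernel_id, spacing)

    k = s.slice_thickness_mm
    if k > 1:
        arr = _slab_average(arr, k)
        mask = _slab_mask(mask, k)
        spacing[0] = spacing[0] * k

    if s.matrix == 512:
        arr = _downsample_inplane(arr, order=1)
        mask = _downsample_inplane(mask.astype(np.uint8), order=0) > 0
        spacing[1] *= 2.0
        spacing[2] *= 2.0

    if s.transmission == "PACS":
        arr = _quantize_12bit(arr)

    sp = (spacing[0], spacing[1], spacing[2])
    return LabeledVolume(
        volume=VolumeGrid(arr, spacing_mm=sp, origin=v.volume.origin),
        mask=RoiMask(mask, spacing_mm=sp, origin=v.mask.origin),
        label=v.label,
        nodule_id=v.nodule_id,
    )


# ---------------------------------------------------------------------------
# Direct feature-panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Variance-component model for per-setting feature tables.

    Feature *f* of subject *i* under setting *s* is

        y_isf = t_if + m_i * g_sf * c_f + d_sf + e_isf

    with subject effect t ~ N(0, between_subject_sd^2), malignancy indicator
    m, class effect c, per-setting effect modulation g (1 everywhere by
    default), fixed setting offsets d, and residual noise e whose variance is
    solved per feature so that the population ICC(A,1) across the settings
    equals ``target_icc`` (exact when g is constant across settings).
    """

    n_subjects: int
    n_features: int
    target_icc: float | Sequence[float] = 0.8
    between_subject_sd: float = 1.0
    setting_offsets: np.ndarray | None = None  # (n_settings, n_features)
    class_effect: float | Sequence[float] = 0.0
    setting_effect_scale: np.ndarray | None = None  # (n_settings,) or (n_settings, n_features)
    malignant_fraction: float = 0.5
    setting_ids: tuple[str, ...] = tuple(s.setting_id for s in SETTINGS)
    seed: int = 0

    def __post_init__(self) -> None:
        icc = np.broadcast_to(np.asarray(self.target_icc, dtype=float),
                              (self.n_features,)).copy()
        if np.any((icc < 0) | (icc > 1)):
            raise ValueError("target_icc must lie in [0, 1]")
        self.target_icc = icc
        self.class_effect = np.broadcast_to(
            np.asarray(self.class_effect, dtype=float), (self.n_features,)
        ).copy()
        if self.between_subject_sd <= 0:
            raise ValueError("between_subject_sd must be > 0")
        k = len(self.setting_ids)
        if self.setting_offsets is not None:
            self.setting_offsets = np.broadcast_to(
                np.asarray(self.setting_offsets, dtype=float),
                (k, self.n_features),
            ).copy()
        if self.setting_effect_scale is not None:
            scale = np.asarray(self.setting_effect_scale, dtype=float)
            if scale.ndim == 1:
                scale = scale[:, None]
            self.setting_effect_scale = np.broadcast_to(
                scale, (k, self.n_features)
            ).copy()


def _residual_sd(spec: PanelSpec) -> np.ndarray:
    """Per-feature residual sd solving ICC(A,1) = target.

    ICC(A,1) converges to sigma_b^2 / (sigma_b^2 + theta_d + sigma_e^2)
    where theta_d = sum_s (d_s - mean d)^2 / (k - 1) is the contribution of
    fixed setting offsets and sigma_b^2 the total between-subject variance
    (subject effect plus, when the effect is homogeneous across settings,
    the class-effect Bernoulli variance).
    """
    k = len(spec.setting_ids)
    p = spec.malignant_fraction
    icc = np.asarray(spec.target_icc)
    homogeneous = spec.setting_effect_scale is None
    c = np.asarray(spec.class_effect)
    sigma_b2 = spec.between_subject_sd ** 2
    sigma_b2 = sigma_b2 + (p * (1 - p) * c ** 2 if homogeneous else 0.0)

    if spec.setting_offsets is not None and k > 1:
        d = spec.setting_offsets
        theta = ((d - d.mean(axis=0)) ** 2).sum(axis=0) / (k - 1)
    else:
        theta = np.zeros(spec.n_features)

    with np.errstate(divide="ignore"):
        total_noise = np.where(icc > 0, sigma_b2 * (1 - icc) / np.where(icc > 0, icc, 1.0),
                               np.inf)
    sigma_e2 = total_noise - theta
    bad = (sigma_e2 < -1e-12) & np.isfinite(total_noise)
    if np.any(bad):
        raise ValueError(
            "setting_offsets too large for the requested target_icc on "
            f"features {np.flatnonzero(bad).tolist()}"
        )
    # icc == 0: pure noise feature; pick noise 100x the signal.
    sigma_e2 = np.where(np.isfinite(sigma_e2), np.clip(sigma_e2, 0.0, None),
                        100.0 * sigma_b2)
    return np.sqrt(sigma_e2)


def simulate_feature_panel(spec: PanelSpec) -> dict[str, pd.DataFrame]:
    """Simulate one feature table per acquisition setting.

    Returns a mapping ``setting_id -> DataFrame`` with columns
    ``nodule_id``, ``setting_id``, ``label`` followed by the feature
    columns ``f0000``..; all tables share subjects and column order.
    """
    k = len(spec.setting_ids)
    ss = np.random.SeedSequence((spec.seed, 17))
    rng = np.random.default_rng(ss)

    n_mal = int(round(spec.n_subjects * spec.malignant_fraction))
    m = np.zeros(spec.n_subjects)
    m[:n_mal] = 1.0
    rng.shuffle(m)

    t = rng.normal(0.0, spec.between_subject_sd,
                   size=(spec.n_subjects, spec.n_features))
    sd_e = _residual_sd(spec)

    offsets = (spec.setting_offsets if spec.setting_offsets is not None
               else np.zeros((k, spec.n_features)))
    scale = (spec.setting_effect_scale if spec.setting_effect_scale is not None
             else np.ones((k, spec.n_features)))
    c = np.asarray(spec.class_effect)

    ids = [f"N{i:04d}" for i in range(spec.n_subjects)]
    labels = np.where(m == 1, "malignant", "benign")
    cols = [f"f{j:04d}" for j in range(spec.n_features)]

    tables: dict[str, pd.DataFrame] = {}
    for s_idx, sid in enumerate(spec.setting_ids):
        e = rng.normal(0.0, 1.0, size=(spec.n_subjects, spec.n_features)) * sd_e
        y = t + m[:, None] * (scale[s_idx] * c) + offsets[s_idx] + e
        df = pd.DataFrame(y, columns=cols)
        df.insert(0, "label", labels)
        df.insert(0, "setting_id", sid)
        df.insert(0, "nodule_id", ids)
        tables[sid] = df
    return tables


#: Per-setting modulation of the fragile features' class effect in the
#: stability benchmark (order S1..S10; 1.0 at the reference S2).  The
#: severity ordering mirrors the relative impact of the reconstruction
#: factors: slice-thickness changes disturb most, PACS export least.
FRAGILE_EFFECT_SCALE = {
    "S1": 0.9, "S2": 1.0, "S3": 0.1, "S4": 0.0, "S5": 0.7,
    "S6": 0.3, "S7": 0.6, "S8": 1.4, "S9": 0.2, "S10": 1.2,
}


def stability_benchmark_panel(n_subjects: int = 400, seed: int = 0,
                              n_per_block: int = 20,
                              class_effect: float = 0.8) -> dict[str, pd.DataFrame]:
    """Feature panel with constructed stability/signal ground truth.

    Three equally sized feature blocks over the ten study settings:

    * robust informative — target ICC 0.95, class effect constant across
      settings (the only setting-robust signal);
    * fragile informative — target ICC 0.2, class effect modulated per
      setting by :data:`FRAGILE_EFFECT_SCALE`;
    * uninformative — target ICC 0.6, no class effect.

    A model restricted to the robust block should hold a near-constant AUC
    across the ten test settings, while one restricted to the fragile
    block swings with the per-setting effect scale.
    """
    n_feat = 3 * n_per_block
    icc = np.concatenate([
        np.full(n_per_block, 0.95),
        np.full(n_per_block, 0.2),
        np.full(n_per_block, 0.6),
    ])
    effect = np.concatenate([
        np.full(n_per_block, class_effect),
        np.full(n_per_block, class_effect),
        np.zeros(n_per_block),
    ])
    setting_ids = tuple(s.setting_id for s in SETTINGS)
    scale = np.ones((len(setting_ids), n_feat))
    for i, sid in enumerate(setting_ids):
        scale[i, n_per_block:2 * n_per_block] = FRAGILE_EFFECT_SCALE[sid]
    spec = PanelSpec(
        n_subjects=n_subjects,
        n_features=n_feat,
        target_icc=icc,
        class_effect=effect,
        setting_effect_scale=scale,
        setting_ids=setting_ids,
        seed=seed,
    )
    return simulate_feature_panel(spec)
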