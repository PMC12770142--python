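"""Extract the radiomic feature vector of one phantom nodule.

Preprocesses (rescale to [0, 2048], resample to 1 mm isotropic) and
extracts the full 644-feature panel: 14 shape + (18 first-order + 24 GLCM)
on the original and 14 derived images (8 wavelet sub-bands, 3 LoG scales,
square, square-root, exponential).
"""

from radstab import ExtractionConfig, PhantomSpec, extract_all, make_phantom_cohort

nodule = make_phantom_cohort(PhantomSpec(n_nodules=1, seed=3))[0]
features = extract_all(nodule.volume, nodule.mask, ExtractionConfig())

print(f"extracted {len(features)} features")
for name in ("original_shape_Maximum3DDiameter", "original_shape_Sphericity",
             "original_firstorder_Entropy", "original_glcm_Contrast",
             "wavelet-HHH_firstorder_Mean", "log-sigma-2-0-mm-3D_glcm_JointEnergy"):
    print(f"  {name:45s} {features[name]:10.4f}")

# Maximum3DDiameter is the equivalent of a caliper measurement (mm);
# sphericity near 1 means a round nodule; entropy/contrast quantify
# intra-nodule texture on the discretized (bin width 25) gray levels.
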