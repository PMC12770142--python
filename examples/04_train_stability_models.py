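"""Train the seven stability-stratum malignancy models on one panel.

Features are stratified by joint ICC across all ten settings, then each
stratum (FULL, S, U, I and the SI / SU / UI ablations) gets its own
pipeline: z-score normalization, MRMR top-k selection, Firth-penalized
logistic regression.  Prints each model's training AUC and the number of
selected features.
"""

from radstab import joint_partition, metrics_row, train_stratum_model
from radstab.classifier import STRATUM_LABELS, apply_stratum_model
from radstab.synthetic import stability_benchmark_panel

tables = stability_benchmark_panel(n_subjects=300, seed=4)
partition, _ = joint_partition(tables)
train = tables["S2"]
y = (train["label"] == "malignant").astype(int).to_numpy()
feat_cols = [c for c in train.columns if c.startswith("f")]

print(f"strata: S={len(partition.stable)}, I={len(partition.intermediate)}, "
      f"U={len(partition.unstable)}")
for label in STRATUM_LABELS:
    feats = sorted(partition.stratum(label) & set(feat_cols))
    model = train_stratum_model(train, y, feats, stratum_label=label, n_select=10)
    prob, pred = apply_stratum_model(model, train)
    row = metrics_row(y, pred, prob)
    print(f"  {label:4s}: {len(feats):2d} candidates -> "
          f"{len(model.feature_names):2d} selected, train AUC {row['auc']:.3f}, "
          f"converged={model.converged}")

# Training AUC alone says nothing about robustness: see example 05 for how
# the same models behave across reconstruction-variant test sets.
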