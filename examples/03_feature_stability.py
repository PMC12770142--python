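"""Score feature stability across acquisition settings with ICC(A,1).

Simulates a feature panel whose true ICC is known by construction, then
estimates per-feature ICC within each reconstruction-factor group and
prints the stable / intermediate / unstable breakdown plus the number of
features stable under all four factors simultaneously.
"""

import numpy as np

from radstab import PanelSpec, intersect_categories, simulate_feature_panel, stability_by_group
from radstab.stability import category_summary

tables = simulate_feature_panel(PanelSpec(
    n_subjects=300, n_features=30, seed=1,
    target_icc=np.r_[np.full(10, 0.95), np.full(10, 0.6), np.full(10, 0.2)],
))

groups = stability_by_group(tables)
for name, records in groups.items():
    summary = category_summary(records)
    print(f"{name:16s} " + "  ".join(
        f"{cat}: {s['count']:2d} ({s['fraction']:5.1%})"
        for cat, s in summary.items()))

always_stable, venn = intersect_categories(groups, "stable")
print(f"\nstable under ALL four factors: {len(always_stable)} features")
print(f"largest Venn region: {max(venn, key=venn.get)} ({max(venn.values())} features)")

# Features generated with ICC 0.95 should land in the stable stratum of
# every group; the ICC-0.2 block should be consistently unstable.
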