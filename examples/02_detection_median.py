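"""Depth-robust heterogeneity via the detection-median statistic.

Two simulated subject groups differ only in dropout (zero inflation).  The
statistic — the median detection fraction of the top-200 average-rank genes —
drops in the high-dropout group, and a one-sided rank-sum test compares groups.
A value of 1 means the population expresses its top program coherently; low
values mean high cell-to-cell heterogeneity.
"""

import numpy as np

from txhet import CohortConfig, detection_group_test, detection_median, simulate_cohort

cfg = CohortConfig(n_genes=400, n_cells_per_condition=150, n_subjects_per_group=5,
                   zero_inflation_by_group=(0.0, 0.4), seed=1)
mats, labels = simulate_cohort(cfg)

meds = {}
for m, lab in zip(mats, labels):
    meds.setdefault(lab, []).append(detection_median(m, k=200))
for lab, v in meds.items():
    print(f"{lab:8s} detection medians: {np.round(v, 3)}")

stat, p = detection_group_test(meds["disease"] + meds["healthy"],
                               ["disease"] * 5 + ["healthy"] * 5, direction="less")
print(f"one-sided rank-sum (disease < healthy): statistic={stat:.1f}, p={p:.4f}")
print("the dropout-burdened group detects its top genes in fewer cells -> more heterogeneous")
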