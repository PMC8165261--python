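"""Select a labeling budget from a ranked list and account the annotation cost.

Builds a synthetic 4,060-sample ranking (the size of a 203-patient
training cohort at 20 slices each), applies the standard recipe —
drop the top and bottom 10%, sample 30% of the full pool — and prints
the cost bounds the recipe implies.
"""

import numpy as np

from qbcal import (
    RankedScoreList,
    UncertaintyRecord,
    annotation_cost,
    exclude_extremes,
    proportion_to_count,
    sample_budget,
)

# a stand-in ranking: strictly decreasing scores over 4,060 samples
n = 4060
records = tuple(
    UncertaintyRecord(f"s{i:05d}", float(n - i), 0.0, float(n - i)) for i in range(n)
)
ranked = RankedScoreList(records)

retained = exclude_extremes(ranked, exclude_top=0.10, exclude_bottom=0.10)
selected = sample_budget(retained, pool_size=n, budget=0.30, seed=0)
print(f"pool size                  : {n}")
print(f"retained after exclusion   : {len(retained)}")
print(f"selected at 30% budget     : {len(selected)}")
for frac in (0.10, 0.30, 0.80):
    print(f"proportion_to_count({frac:.2f})  : {proportion_to_count(frac, n)}")

report = annotation_cost(labeled_fraction=0.30, budget_fraction=0.30)
print()
print(report)
print(
    "\nThe 1,218 selected samples are 30% of the pool. Depending on how much the\n"
    "selection overlaps the 30% seed already labeled, between 30% and 60% of the\n"
    "pool ever needs labels, i.e. 40-70% of the annotation cost is saved."
)
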