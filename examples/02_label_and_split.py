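"""Threshold VTN fractions into WH-CAF-high/low labels and split 3:1:1.

The threshold is the cohort median; tumors (not images) are assigned to
splits so no tumor's image pairs leak across train/val/test.
"""

import swecaf

records = swecaf.sample_cohort(swecaf.CohortConfig(n_tumors=105, seed=2))
manifest = swecaf.label_and_split(records, swecaf.LabelingConfig(threshold_method="median", seed=2))

print(f"threshold (median VTN fraction): {manifest.threshold_value:.4f}")
for split, counts in manifest.counts().items():
    total = counts["high"] + counts["low"]
    print(f"{split:>5}: {total:3d} tumors  (high {counts['high']}, low {counts['low']})")
print("105 tumors at 3:1:1 -> 63/21/21, each split class-balanced within one tumor")
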