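#!/usr/bin/env python
"""Expression-area quantification and the nonparametric comparison panel.

Reports the 2-STD YFP pixel counts per animal, the label-shuffle control
(observed group difference vs permuted-label null), and the rank-sum
comparison table, including the electrode-integrity first-vs-last-trial
check for ICMS.
"""
import pandas as pd

counts = pd.read_csv("results/study/yfp_counts.csv")
shuffle = pd.read_csv("results/study/yfp_shuffle.csv").iloc[0]
stats = pd.read_csv("results/study/stats.csv")

print(counts.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\nobserved long-short difference: {shuffle.observed:.1f} pixels; "
      f"shuffled null {shuffle.shuffle_mean:.1f} +/- {shuffle.shuffle_std:.1f} "
      f"({shuffle.z_score:.1f} STD above the null)")
print("\ncomparison panel:")
print(stats[["label", "test", "p_value", "p_adjusted"]].to_string(
    index=False, float_format=lambda v: f"{v:.4g}"))
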