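"""Extract depolarization-evoked calcium features and compare genotypes.

Simulates KCl-evoked traces at the day-7 study conditions (wild-type mean
peak dF/F0 1.222 vs homozygous-mutant 1.383), extracts per-ROI features in the
0-20 s poststimulus window, and runs the two-sided rank-sum comparison.
"""

from compartquant.calcium import compare_groups, features_table
from compartquant.sim.calcium import generate_calcium_traces, d7_depolarization_config

ts = generate_calcium_traces(d7_depolarization_config(n_per_group=40, seed=1))
features = features_table(ts.traces)   # onset auto-detected from the mean trace

summary = features.groupby("group")[["peak", "auc", "rise_time_s"]].mean().round(3)
resp = features.groupby("group")["responder"].mean().round(2)
print("per-genotype means over 40 ROIs each:")
print(summary)
print("\nresponder fraction (peak > baseline mean + 3 SD):")
print(resp)

wt = features[features.group == "wildtype"]["peak"]
mut = features[features.group == "hom_mutant"]["peak"]
res = compare_groups(wt, mut)
print(f"\nrank-sum test on peak dF/F0: W = {res.statistic:.0f}, p = {res.p:.4f}")
print("The mutant group mean should sit near 1.38 and the wild type near 1.22;")
print("a small p indicates the planted group difference was detected.")
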