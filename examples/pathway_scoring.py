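"""Normalize counts and score pathway activity, on numbers small enough
to follow by hand.

The 3-gene x 2-sample matrix has sample B exactly double sample A, so the
median-of-ratios size factors come out (1/sqrt(2), sqrt(2)) and the
normalized expression of the two samples coincides.
"""

import numpy as np

import splicecor as sc

counts = sc.CountsMatrix(
    ["g1", "g2", "g3"], ["A", "B"],
    np.array([[10, 20], [100, 200], [4, 8]]),
)
s = sc.size_factors(counts)
print(f"size factors: A = {s[0]:.4f}, B = {s[1]:.4f}  (1/sqrt2, sqrt2)")

expr = sc.normalize_and_log(counts, s)
print("normalized log2 values (identical columns after depth correction):")
print(expr.to_frame().round(3))

# mean-z scoring over a larger simulated cohort
cfg = sc.default_cohort_config(seed=4, n_coupled=0, n_events=10,
                               n_pathway_genes=50, n_background_genes=100)
cohort_counts, meta, _, truth = sc.simulate_cohort(cfg)
pathway = sc.GeneSet("PWY", [f"PWY{i + 1:04d}" for i in range(50)])
sv = sc.pathway_score(
    sc.normalize_and_log(cohort_counts, sc.size_factors(cohort_counts)), pathway)
by_stage = sv.to_series().groupby(meta.table["stage"]).mean()
by_stage = by_stage.reindex(["normal", "benign", "tumor"])
print("\nmean activity score per stage (should rise normal -> benign -> tumor):")
print(by_stage.round(3).to_string())
# mean-z scores are centered at 0 across the scoring group, so stages
# below/above the cohort average score negative/positive.
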