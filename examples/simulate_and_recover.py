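"""Simulate a staged cohort and recover the activity-coupled exons.

A 300-sample cohort over three disease stages (normal -> benign -> tumor)
is simulated with 25 of 500 cassette exons coupled negatively to a latent
pathway activity. The full pipeline — median-of-ratios normalization,
mean-z activity scoring over the 50-gene pathway, PSI quantification,
per-cohort Pearson correlation with BH adjustment — is then asked to find
those exons again.
"""

import numpy as np

import splicecor as sc

cfg = sc.default_cohort_config(
    seed=1, n_coupled=25, b1_range=(-2.0, -1.0), n_events=500,
    coverage_mean=100.0, n_pathway_genes=50, n_background_genes=200,
)
counts, meta, table, truth = sc.simulate_cohort(cfg)
pathway = sc.GeneSet("PWY", [f"PWY{i + 1:04d}" for i in range(50)])

scores, psi, records = sc.activity_splicing_correlation(counts, meta, table, pathway)

r_truth, _ = sc.pearson_r_p(scores.scores, truth.activity.loc[scores.sample_ids])
coupled = set(truth.coupled_event_ids)
hits = records[records.target_id.isin(coupled)]
nulls = records[~records.target_id.isin(coupled)]
recovered = ((hits["p_adj"] < 0.05) & (hits["r"] < 0)).sum()
false_flags = (nulls["p_adj"] < 0.05).sum()

print(f"samples: {len(scores.sample_ids)}, events: {len(psi.event_ids)}")
print(f"score vs latent activity: r = {r_truth:.3f}")
print(f"coupled exons recovered (p_adj < 0.05, negative r): {recovered} / {len(coupled)}")
print(f"null exons flagged: {false_flags} / {len(nulls)}")
# A high truth correlation means the 50-gene score is a faithful proxy for
# the latent activity; recovery near 25/25 with few false flags shows the
# correlation stage separates coupled from null exons at this coverage.
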