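"""Compare splicing programs across perturbations.

Three two-group experiments share a block of commonly responsive exons
(the same planted indices), mimicking perturbations of cooperating
regulators. Events are matched by exon coordinates (IDs are ignored),
then summarized as three-way Venn counts, a hypergeometric enrichment
p-value, and a Jaccard-ranked similarity table.
"""

import splicecor as sc
from splicecor.splicing import differential_splicing_test, filter_significant_events

programs = {}
for name, seed in [("regulator_A", 1), ("regulator_B", 2), ("regulator_C", 3)]:
    table, meta, _ = sc.simulate_two_group_experiment(3, 200, 40, 0.3, 100, seed=seed)
    rec = differential_splicing_test(table, meta)
    sig = filter_significant_events(rec)
    programs[name] = table.events[table.events["event_id"].isin(sig)]

venn = sc.three_way_venn(*programs.values())
print("three-way Venn regions:", venn)

res = sc.overlap_result(programs["regulator_A"], programs["regulator_B"], universe=200)
print(f"A vs B: |A|={res.size_a} |B|={res.size_b} overlap={res.overlap} "
      f"universe={res.universe}")
print(f"hypergeometric P(X >= {res.overlap}) = {res.p_hyper:.3e}, "
      f"Jaccard = {res.jaccard:.3f}")

ranked = sc.pairwise_jaccard_matrix(
    programs["regulator_A"],
    {k: v for k, v in programs.items()},
)
print("\nprograms ranked by similarity to regulator_A:")
print(ranked.round(3).to_string(index=False))
# The planted shifts sit at the same coordinates in every run, so the
# triple-overlap region is large and the enrichment p-value is extreme —
# the signature of perturbations acting on one shared splicing program.
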