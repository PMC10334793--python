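"""Two-group differential splicing: plant PSI shifts, test, filter.

Simulates a knockout-style design (3 control vs 3 perturbed samples,
coverage ~100 junction reads per event) with a |dPSI| = 0.3 shift planted
in 40 of 200 exons, then applies the pooled-binomial likelihood-ratio
test and the standard significance filters (mean junction reads > 10,
|dPSI| > 0.05, FDR < 0.05).
"""

import splicecor as sc

table, meta, truth = sc.simulate_two_group_experiment(
    n_per_group=3, n_events=200, n_changed=40, delta_psi=0.3,
    coverage=100, seed=11,
)
records = sc.differential_splicing_test(table, meta, group_col="condition")
significant = sc.filter_significant_events(records)

planted = set(truth.event_params.loc[truth.event_params["coupled"], "event_id"])
print(f"events tested: {int(records['tested'].sum())} / {len(records)}")
print(f"significant events: {len(significant)}")
print(f"planted shifts recovered: {len(significant & planted)} / {len(planted)}")
print(f"false positives: {len(significant - planted)}")

top = records.loc[records["event_id"].isin(significant)].nsmallest(3, "fdr")
print("\nstrongest three calls:")
print(top[["event_id", "psi_group1", "psi_group2", "delta_psi", "fdr"]]
      .round(4).to_string(index=False))
# delta_psi is control minus perturbed inclusion; at this coverage a 0.3
# shift is essentially always detected while null events stay quiet.
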