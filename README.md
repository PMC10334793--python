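# splicecor

Pathway-activity-guided analysis of cassette-exon splicing in bulk RNA-seq
cohorts — for computational biologists who want to ask, across a disease
spectrum, *which exons' inclusion tracks the activity of a transcriptional
program*, and to compare the splicing programs that different regulator
perturbations produce.

## What it computes

Given a gene-level count matrix, sample metadata (cohort and disease
stage/condition), a hallmark-style gene set, and skipped-exon junction
counts (rMATS JC dialect), the package chains:

1. **Normalization** — median-of-ratios size factors
   *s*<sub>j</sub> = median<sub>g</sub>( *k*<sub>gj</sub> / (∏<sub>j'</sub> *k*<sub>gj'</sub>)<sup>1/n</sup> ),
   then log2(*k*/*s* + 1).
2. **Activity scoring** — per-sample pathway activity as the mean of
   per-gene z-scores over the gene set (default), or a rank-based
   single-sample enrichment score; scoring group = cohort.
3. **PSI quantification** — ψ = (I/l<sub>I</sub>) / (I/l<sub>I</sub> + S/l<sub>S</sub>)
   from inclusion/skipping junction reads with effective form lengths.
4. **Correlation** — per (event, cohort): Pearson r of ψ against the
   activity score, two-sided t-based p, Benjamini–Hochberg adjustment
   within cohort; pairwise deletion of missing ψ; splicing-factor
   expression can be correlated the same way.
5. **Differential splicing** — two-group pooled-binomial likelihood-ratio
   test of H₀: ψ₁ = ψ₂ (read-level inclusion probability
   q(ψ) = ψl<sub>I</sub> / (ψl<sub>I</sub> + (1−ψ)l<sub>S</sub>)), with the standard
   significance filters: mean junction reads > 10, |Δψ| > 0.05, FDR < 0.05.
6. **Program overlap** — coordinate-keyed event matching across
   comparisons, three-way Venn counts, one-sided hypergeometric
   enrichment P(X ≥ k) computed in log space, and Jaccard-ranked
   program similarity.
7. **Cis-element mapping** — maximal G-run (≥3 consecutive G; hnRNP H/F
   motif) scanning, 18-mer antisense-oligo tiling design, and
   silencer/enhancer calls from replicate PSI vs a nontargeting control
   (t-test; raw and BH-adjusted calls).

A synthetic-cohort generator (`splicecor.synthetic`) produces staged
cohorts with latent pathway activity, activity-responsive pathway genes,
logit-coupled exon PSI, and binomially sampled junction reads — with the
ground truth returned alongside — so the whole pipeline is testable
without any external download.

## Worked example

```bash
python examples/simulate_and_recover.py
```

prints

```
samples: 300, events: 500
score vs latent activity: r = 0.996
coupled exons recovered (p_adj < 0.05, negative r): 25 / 25
null exons flagged: 1 / 475
```

The cohort has 100 samples in each of three stages whose latent activity
rises with progression; 25 of 500 exons are coupled to that activity with
negative logit slopes (inclusion repressed as activity rises). The score
built from the 50 pathway genes correlates at r ≈ 0.996 with the hidden
activity, all 25 coupled exons are recovered at BH-adjusted p < 0.05 with
the planted sign, and 1 of 475 null exons is flagged — consistent with
the 5% FDR target.

Other capabilities are demonstrated one per script in `examples/`
(pathway scoring, differential splicing, program overlap, ASO tiling), and
a thin CLI mirrors them (`splicecor --help`).

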