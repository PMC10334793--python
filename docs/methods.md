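# Methods

## The model

The package studies cassette (skipped) exons: an exon either spliced in
between two constitutive flanks or skipped entirely. Its inclusion level
ψ (percent spliced in) is estimated from junction-spanning reads as the
length-normalized ratio

    psi = (I / lI) / (I / lI + S / lS)

where I and S count inclusion- and skipping-junction reads and lI, lS are
the effective lengths of the inclusion and skipping forms (a longer form
catches proportionally more reads). Equivalently, conditional on the
total T = I + S, inclusion reads are Binomial(T, q) with

    q(psi) = psi * lI / (psi * lI + (1 - psi) * lS),

a monotone bijection between q and ψ. This binomial read model underlies
both the simulator and the differential test.

The driving covariate is a per-sample *pathway activity*: the coordinated
expression of a hallmark gene set (e.g. the targets of a proto-oncogenic
transcription factor) summarized to one score per sample. The scientific
question is which exons' ψ, and which splicing factors' expression,
co-vary with that score across a cohort's disease spectrum.

## Activity scoring

Two single-sample realizations of a hallmark enrichment score are
provided; downstream code treats the score vector opaquely, so the
correlation analysis is method-agnostic.

- **mean-z (default).** Counts are depth-normalized with median-of-ratios
  size factors (genes with any zero count are excluded from the median;
  if none survive, an error advises a pseudo-reference fallback), then
  log2(x+1)-transformed. Each gene is z-scored across the scoring group
  using the sample (n−1) standard deviation — a convention that must be
  fixed for reproducibility; zero-variance genes contribute 0. A sample's
  score is the mean z over gene-set genes present (absent genes are
  dropped, counted, and warned about; fewer than 5 present is an error).
  Scores are exactly mean-0 within the scoring group.
- **rank-ssgsea.** Per sample, genes are ranked by expression and the
  score is the normalized weighted Kolmogorov–Smirnov running-sum
  statistic of the gene set (weight rank^0.25). Rank-based, hence robust
  to monotone transforms of expression.

The scoring group defaults to the cohort (a tumor type with its matched
normals), because cross-cohort depth and composition differences would
otherwise dominate the z-scores; a cross-cohort flag exists. Whether to
z-score within or across cohorts is genuinely open for real data; both
are supported. Size factors are computed on the full count matrix even
when only a gene subset (e.g. a splicing-factor panel) is analyzed —
whole-matrix factors are the statistically standard choice; pre-subset
the matrix to get the alternative.

## Correlation

Per (target, cohort): Pearson r between the target (event ψ or gene
expression) and the activity score, after pairwise deletion of missing
values (never imputation); two-sided p from t = r·sqrt((n−2)/(1−r²));
Benjamini–Hochberg adjustment **within** cohort (the cohort is the
multiple-testing family; pan-cohort adjustment is available by pooling
the records). Records with n < 10 pairs or zero variance keep r when it
is computable but have p withheld and are flagged unevaluable — Pearson
p-values are unreliable at tiny n. A permutation p-value
(1 + #{|r_perm| ≥ |r_obs|})/(B+1) is available as a robustness check.

Note that BH adjustment is *not* idempotent: re-adjusting an adjusted
vector inflates it again, because the m/j step-up factors re-apply. The
true invariants — monotone in the sorted order, bounded in [p, 1] — are
what the tests assert.

## Differential splicing

Replicate junction counts are pooled within each group (missing
replicates dropped, never imputed), and a 1-df likelihood-ratio test of
H₀: ψ₁ = ψ₂ is computed under the binomial read model. Because q ↔ ψ is
monotone, the alternative maximizes at q̂_g = I_g/(I_g+S_g) per group and
the null at the pooled fraction; the statistic is 2(llₐ − ll₀) against
χ²₁. Pooling is a deliberate simplification of hierarchical
replicate models: the reproducible contract here is the significance
*filters*, not a specific tool's internals. The worked value frozen in
the tests — pooled 30/70 vs 50/50 with equal form lengths gives
LRT = 8.4024, p = 0.00375 — was verified by brute-force grid
maximization of the likelihood before the analytic form was written.

Significant events satisfy **mean junction reads > 10, |Δψ| > 0.05, and
FDR < 0.05**, all strict. "Junction reads per event" is interpreted as
the mean of I+S across all samples of both groups — the most common
reading; min/sum summaries are accepted via a parameter since the
convention is not universal.

## Program overlap

Event identity across comparisons is purely coordinate-based
(chrom, strand, exon start/end; strict mode adds the flanking-exon
coordinates), since event IDs differ between quantifier runs; the
direction of Δψ is ignored when intersecting. Overlap significance is
the one-sided hypergeometric upper tail P(X ≥ k), computed by logsumexp
over log-pmf terms so that enrichment p-values at the 1e-140…1e-300
scale remain representable in a double. The universe N is a required,
logged input; the recommended default is the set of events quantifiable
(passing the coverage filter) in both comparisons — the most defensible
background when the true universe is unknown. Jaccard |A∩B|/|A∪B| ranks
program similarity; J of two empty sets is defined 0 with a warning.

## Cis-element mapping

G-runs are **maximal** runs of ≥3 consecutive G on the sense (pre-mRNA)
strand — the binding motif of hnRNP H/F, which enhances splicing from a
downstream intron — classed G3 (exactly 3) vs G4plus (≥4). Maximal-run
semantics avoid double counting; whether real motif tallies should count
runs ≥3 or only lengths {3,4} is ambiguous in the field, and the
min-length is a parameter.

ASO tiles are 18-mers (parameter) walking a window of exon plus intronic
flanks; without a schedule they abut from position 0 and any trailing
sub-tile stretch is left uncovered; a schedule of start offsets
reproduces panels with deliberate overlaps. Tile sequences are reverse
complements of the window slice; oligo chemistry is metadata only, not
modeled. Element calls compare replicate PSI under each ASO with the
nontargeting control by a two-sided equal-variance t-test (Welch via
flag): a significant inclusion *increase* means the ASO blocked a
silencer, a *decrease* an enhancer. Per-ASO raw-alpha calls (matching
the per-comparison significance stars customary for such panels) are
reported alongside BH-adjusted calls across the panel — fidelity plus
rigor. Genomic lifting of tile and G-run intervals is strand-aware
(minus-strand windows mirror-map; the transform and its inverse are
round-trip tested).

## The synthetic cohort generator

What it emulates: a multi-stage disease spectrum in which a latent
pathway activity a_i ~ Normal(stage mean, stage sd) rises with
progression (defaults: three stages normal/benign/tumor, 100 samples
each, means 0/1/2, sd 0.5); pathway genes with mean counts
μ_g·2^(β_g·a_i) (default β = 1 per unit activity, baselines uniform on
log10 counts 2–3); activity-independent background genes; exon inclusion
coupled through a logit link ψ_i = logistic(b0 + b1·a_i), b1 = 0 for
null events; per-event total junction reads negative binomial with mean
100 and dispersion θ = 10 (variance μ + μ²/θ — the standard RNA-seq
overdispersion form; no generative model is canonical here, only the
data shapes), and inclusion reads Binomial(T, q(ψ)) with rMATS-typical
form lengths 198/99. Coupled events default to slopes b1 ∈ [−2, −0.5]
(the repressed-exon direction) with intercepts centered so the dynamic
range straddles the cohort mean activity — an effect-size choice made
once for the generator, not a claim about any particular dataset.
Gaussian per-stage activity is a desk-scale, parameter-controlled choice
rather than an empirical cohort distribution.

What it does **not** emulate — and hence what passing tests do not show
about real data: batch effects and library-preparation artifacts,
gene–gene correlation beyond the shared activity factor, isoform-level
read assignment ambiguity, cohort-specific PSI distributions, mapping
bias, or hierarchical replicate structure. Recovery rates on the
simulator demonstrate the statistical machinery is correct and
calibrated, not that any particular biological effect size is detectable
in a given cohort.

The two-group simulator draws baselines ψ₁ ~ Uniform(0.1, 0.9) and
shifts ±Δψ (clamped to [0.01, 0.99]; baselines whose clamping would
erode the planted shift are resampled with a logged notice). The
sequence simulator plants maximal G-runs into a {A,C,T} background, so
recovery is exact by construction.

One RNG stream per call, explicitly seeded, no global state: identical
seeds give byte-identical outputs.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere (BED convention); BED
  interval length is end − start.
- rMATS JC dialect only; IncLevel columns, when present, are re-derived
  from counts and compared within ±0.001 (rMATS rounds to 3 decimals) —
  on mismatch the derived value wins with a warning, since counts are
  the source of truth. "NA" replicates become missing ψ downstream.
- MXE/A5SS/A3SS/RI event types are out of scope; only SE tables are read.
- The supplementary-XLSX reader is permissive and column-name-driven
  (one sheet per comparison), because such layouts vary.
- All text I/O is UTF-8, tab-separated, with '#' comment lines skipped.
- Problem sizes in the test suite and acceptance script (cohorts of 300
  samples, 500–2,000 events, coverage 100, 5 seeds for calibration
  averages) were chosen as the smallest sizes at which the calibration
  and power properties are stable; all checks run in seconds.

## Known limitations

- The pooled LRT ignores between-replicate overdispersion; with many
  replicates per group it is anti-conservative relative to hierarchical
  models. The filters (reads, |Δψ|, FDR) absorb much of this in
  practice.
- mean-z and rank-ssgsea scores are not numerically interchangeable with
  any specific external enrichment tool; only their correlation behavior
  is contracted.
- Hypergeometric enrichment assumes exchangeable events within the
  universe; coordinated splicing of co-regulated exon families violates
  this, so extreme p-values should be read as rankings, not literal
  probabilities.
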