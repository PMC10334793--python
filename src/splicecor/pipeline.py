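"""End-to-end convenience: counts + junction table + gene set -> per-event
correlation records.

Chains the stages the library exposes individually: median-of-ratios
normalization, per-cohort activity scoring, PSI quantification, and the
per-cohort Pearson/BH correlation of each event's PSI with the score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity import normalize_and_log, pathway_score, size_factors
from .correlate import correlate_psi_with_activity
from .datatypes import (
    ActivityScoreVector,
    CountsMatrix,
    GeneSet,
    SampleMetadata,
    SeEventTable,
)
from .splicing import build_psi_matrix

__all__ = ["score_per_cohort", "activity_splicing_correlation"]


def score_per_cohort(
    counts: CountsMatrix,
    meta: SampleMetadata,
    geneset: GeneSet,
    method: str = "mean-z",
) -> ActivityScoreVector:
    """Activity scores computed within each cohort separately, then concatenated.

    The scoring group is the cohort (a tumor type's disease spectrum), so
    mean-z scores are centered within every cohort.
    """
    expr = normalize_and_log(counts, size_factors(counts))
    cohorts = meta.table["cohort"]
    pieces = []
    for cohort in pd.unique(cohorts):
        samples = [s for s in expr.sample_ids if s in cohorts.index and cohorts[s] == cohort]
        pieces.append(pathway_score(expr, geneset, group=samples, method=method))
    sample_ids = [s for p in pieces for s in p.sample_ids]
    scores = np.concatenate([p.scores for p in pieces])
    return ActivityScoreVector(sample_ids, geneset.name, scores,
                               n_genes_used=pieces[0].n_genes_used)


def activity_splicing_correlation(
    counts: CountsMatrix,
    meta: SampleMetadata,
    table: SeEventTable,
    geneset: GeneSet,
    method: str = "mean-z",
    min_n: int = 10,
):
    """Full pipeline: score -> PSI -> correlate -> BH (within cohort).

    Returns (scores, psi, records) where records is the correlation
    DataFrame with one row per (event, cohort).
    """
    scores = score_per_cohort(counts, meta, geneset, method=method)
    psi = build_psi_matrix(table)
    records = correlate_psi_with_activity(psi, scores, meta, min_n=min_n)
    return scores, psi, records
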