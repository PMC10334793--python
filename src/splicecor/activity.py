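"""Count normalization and per-sample pathway-activity scoring.

Normalization uses the median-of-ratios size factors: for each gene a
geometric mean across samples is the reference, and a sample's size
factor is the median of its count/reference ratios over genes with no
zero count. Activity scoring offers two single-sample realizations of a
hallmark enrichment score:

``mean-z`` (default)
    Per gene, z-score the log2-normalized expression across the scoring
    group (sample standard deviation, ddof=1); a sample's score is the
    mean z over the gene-set genes present. Zero-variance genes
    contribute 0.

``rank-ssgsea``
    Per sample, rank all genes by expression and take the normalized
    weighted Kolmogorov-Smirnov running-sum statistic of the gene set
    (weight = rank^tau, tau = 0.25), a rank-based single-sample
    enrichment score.

Downstream correlation consumes the score vector opaquely, so the two
methods are interchangeable there.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    ActivityScoreVector,
    CountsMatrix,
    GeneSet,
    NormalizedExpression,
    SpliceCorError,
)

__all__ = ["size_factors", "normalize_and_log", "pathway_score", "MIN_GENES_DEFAULT"]

#: minimum gene-set genes that must be present in the matrix to score
MIN_GENES_DEFAULT = 5


def size_factors(counts: CountsMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive scalar per sample.

    Genes with a zero count in any sample are excluded from the median
    (their geometric mean would vanish). Raises if no gene survives,
    advising a pseudo-reference fallback on such sparse matrices.
    """
    c = counts.counts.astype(float)
    nonzero = (c > 0).all(axis=1)
    if not nonzero.any():
        raise SpliceCorError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined — consider a pseudo-reference (e.g. add-one) fallback"
        )
    c = c[nonzero]
    log_geomean = np.log(c).mean(axis=1)
    ratios = np.exp(np.log(c) - log_geomean[:, None])
    return np.median(ratios, axis=0)


def normalize_and_log(counts: CountsMatrix, factors: np.ndarray) -> NormalizedExpression:
    """log2(count / s_j + 1) expression matrix."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(counts.sample_ids),):
        raise SpliceCorError("one size factor per sample required")
    if (factors <= 0).any():
        raise SpliceCorError("size factors must be positive")
    values = np.log2(counts.counts / factors[None, :] + 1.0)
    return NormalizedExpression(counts.gene_ids, counts.sample_ids, values, factors)


def _mean_z_scores(values: np.ndarray) -> np.ndarray:
    # values: geneset genes x samples (one scoring group)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True) if values.shape[1] > 1 else np.zeros_like(mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mu) / sd, 0.0)
    return z.mean(axis=0)


def _rank_ssgsea_scores(values: np.ndarray, in_set: np.ndarray, tau: float = 0.25) -> np.ndarray:
    """Weighted KS running-sum enrichment per sample (normalized by n_genes)."""
    n_genes, n_samples = values.shape
    scores = np.empty(n_samples)
    for j in range(n_samples):
        order = np.argsort(-values[:, j], kind="stable")
        member = in_set[order]
        ranks = np.arange(n_genes, 0, -1, dtype=float)  # high expression = high rank
        w = ranks**tau
        w_in = np.where(member, w, 0.0)
        denom_in = w_in.sum()
        n_out = n_genes - member.sum()
        step_in = np.cumsum(w_in) / denom_in
        step_out = np.cumsum(~member) / n_out
        scores[j] = (step_in - step_out).sum() / n_genes
    return scores


def pathway_score(
    expr: NormalizedExpression,
    geneset: GeneSet,
    group=None,
    method: str = "mean-z",
    min_genes: int = MIN_GENES_DEFAULT,
) -> ActivityScoreVector:
    """Per-sample activity score for a gene set within a scoring group.

    ``group`` restricts scoring to a subset of samples (the default group
    is all samples; per-cohort scoring passes each cohort's samples in
    turn). Gene-set genes absent from the matrix are dropped with a
    warning; fewer than ``min_genes`` present is an error.
    """
    if group is None:
        group = expr.sample_ids
    group = list(group)
    missing_samples = [s for s in group if s not in expr.sample_ids]
    if missing_samples:
        raise SpliceCorError(f"samples not in expression matrix: {missing_samples[:5]}")

    present = [g for g in geneset.genes if g in expr.gene_ids]
    absent = sorted(set(geneset.genes) - set(present))
    if len(present) < min_genes:
        raise SpliceCorError(
            f"only {len(present)} gene-set genes present (floor {min_genes}); "
            f"missing: {absent[:10]}"
        )
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) of set {geneset.name!r} absent from the matrix: {absent[:5]}"
        )

    col_idx = [expr.sample_ids.index(s) for s in group]
    if method == "mean-z":
        row_idx = [expr.gene_ids.index(g) for g in sorted(present)]
        scores = _mean_z_scores(expr.values[np.ix_(row_idx, col_idx)])
    elif method == "rank-ssgsea":
        in_set = np.array([g in geneset.genes for g in expr.gene_ids])
        scores = _rank_ssgsea_scores(expr.values[:, col_idx], in_set)
    else:
        raise SpliceCorError(f"unknown scoring method {method!r}")

    return ActivityScoreVector(group, geneset.name, scores, n_genes_used=len(present))
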