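"""Overlap of splicing programs: event matching, hypergeometric enrichment,
Jaccard similarity, and three-way Venn counts.

Event identity across comparisons is coordinate-based: rMATS event IDs
differ between runs, so two events match when (chrom, strand, exon_start,
exon_end) agree ('default' mode) or additionally the flanking-exon
coordinates agree ('strict' mode). The direction of the PSI change is
deliberately ignored when intersecting.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .datatypes import OverlapResult, SeEventTable, SpliceCorError

__all__ = [
    "event_key",
    "match_events",
    "hypergeometric_tail",
    "jaccard_index",
    "overlap_result",
    "pairwise_jaccard_matrix",
    "three_way_venn",
]

_DEFAULT_KEY = ["chrom", "strand", "exon_start", "exon_end"]
_STRICT_KEY = _DEFAULT_KEY + ["upstream_es", "upstream_ee", "downstream_es", "downstream_ee"]


def event_key(row, mode: str = "default") -> tuple:
    cols = _DEFAULT_KEY if mode == "default" else _STRICT_KEY
    return tuple(row[c] for c in cols)


def _keyed(events, mode: str) -> frozenset:
    if isinstance(events, SeEventTable):
        events = events.events
    if isinstance(events, pd.DataFrame):
        cols = _DEFAULT_KEY if mode == "default" else _STRICT_KEY
        missing = [c for c in cols if c not in events.columns]
        if missing:
            raise SpliceCorError(f"event table lacks key columns {missing}")
        return frozenset(map(tuple, events[cols].itertuples(index=False, name=None)))
    return frozenset(events)


def match_events(set_a, set_b, mode: str = "default", force: bool = False):
    """Key two event collections and intersect them.

    Accepts SeEventTables, event DataFrames, or pre-keyed iterables. When
    both inputs are SeEventTables their genome_build labels must match
    (string equality; override with force=True).
    """
    if mode not in ("default", "strict"):
        raise SpliceCorError(f"unknown match mode {mode!r}")
    if (
        isinstance(set_a, SeEventTable)
        and isinstance(set_b, SeEventTable)
        and set_a.genome_build != set_b.genome_build
        and not force
    ):
        raise SpliceCorError(
            f"genome build mismatch: {set_a.genome_build!r} vs {set_b.genome_build!r} "
            "(pass force=True to override)"
        )
    a, b = _keyed(set_a, mode), _keyed(set_b, mode)
    return a, b, a & b


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, K marked, n drawn).

    Computed by logsumexp over log-pmf terms so that enrichment p-values
    at the 1e-300 scale remain representable.
    """
    for name, v in [("k", k), ("K", K), ("n", n), ("N", N)]:
        if v < 0:
            raise SpliceCorError(f"{name} must be >= 0")
    if K > N or n > N:
        raise SpliceCorError("K and n cannot exceed the universe N")
    if k <= max(0, K + n - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    ks = np.arange(k, hi + 1)
    log_terms = stats.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; 0 (with a warning) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def overlap_result(set_a, set_b, universe: int, mode: str = "default", force: bool = False) -> OverlapResult:
    """Full two-set overlap summary under a stated universe size.

    The universe N is a required, logged input; the recommended default is
    the number of events quantifiable (passing the coverage filter) in
    BOTH comparisons.
    """
    a, b, inter = match_events(set_a, set_b, mode=mode, force=force)
    if universe < len(a | b):
        raise SpliceCorError(f"universe {universe} smaller than |A u B| = {len(a | b)}")
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        overlap=len(inter),
        universe=universe,
        p_hyper=hypergeometric_tail(len(inter), len(a), len(b), universe),
        jaccard=jaccard_index(a, b),
    )


def pairwise_jaccard_matrix(reference_set, named_sets: dict, mode: str = "default") -> pd.DataFrame:
    """Jaccard of a reference event set against each named set, ranked.

    Sorted by descending J, ties broken by set name. Useful for ranking
    perturbation-derived splicing programs by similarity to a reference
    program.
    """
    if len(named_sets) < 2:
        raise SpliceCorError("need at least two sets to rank")
    ref = _keyed(reference_set, mode)
    rows = [(name, jaccard_index(ref, _keyed(s, mode))) for name, s in named_sets.items()]
    df = pd.DataFrame(rows, columns=["set_name", "jaccard"])
    return df.sort_values(["jaccard", "set_name"], ascending=[False, True]).reset_index(drop=True)


def three_way_venn(set_a, set_b, set_c, mode: str = "default") -> dict[str, int]:
    """Counts of the 7 Venn regions; values sum to |A u B u C|."""
    a, b, c = _keyed(set_a, mode), _keyed(set_b, mode), _keyed(set_c, mode)
    abc = a & b & c
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(abc),
    }
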