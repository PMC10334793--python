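"""Core in-memory containers shared across the pipeline.

All genomic intervals throughout the package are 0-based, half-open
(BED convention): an exon spanning reference bases 101..182 is stored as
``(exon_start=100, exon_end=182)`` and has length ``end - start``.

Junction counts may be missing for individual samples (rMATS emits ``NA``
for uncovered replicates); missing counts are stored as NaN in float
arrays and propagate to missing PSI downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountsMatrix",
    "SampleMetadata",
    "GeneSet",
    "SeEventTable",
    "PsiMatrix",
    "ActivityScoreVector",
    "NormalizedExpression",
    "OverlapResult",
    "GRun",
    "AsoTile",
    "ElementCall",
    "SpliceCorError",
    "FormatError",
]


class SpliceCorError(ValueError):
    """Base class for validation and format errors raised by this package."""


class FormatError(SpliceCorError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SpliceCorError(f"duplicate {what}: {dup[:5]}")


@dataclass
class CountsMatrix:
    """Gene-level read counts, genes x samples, non-negative integers."""

    gene_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise SpliceCorError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise SpliceCorError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise SpliceCorError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "CountsMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return CountsMatrix(list(genes), self.sample_ids, self.counts[idx])


@dataclass
class SampleMetadata:
    """Per-sample annotations: cohort (tumor type) and stage/condition.

    ``table`` is indexed by sample_id and must carry at least a ``cohort``
    column plus a ``stage`` or ``condition`` column (the grouping column
    used downstream is chosen by name, so extra columns are harmless).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        _check_unique(t.index, "sample ids")
        if "cohort" not in t.columns:
            raise SpliceCorError("metadata must have a 'cohort' column")
        if not ({"stage", "condition"} & set(t.columns)):
            raise SpliceCorError("metadata must have a 'stage' or 'condition' column")
        if t.isna().any().any():
            raise SpliceCorError("metadata contains missing values")
        self.table = t

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def group_labels(self, column: str) -> pd.Series:
        if column not in self.table.columns:
            raise SpliceCorError(f"no metadata column {column!r}")
        return self.table[column]


@dataclass
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise SpliceCorError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)


#: columns describing event geometry, in canonical order
EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "gene_symbol",
    "chrom",
    "strand",
    "exon_start",
    "exon_end",
    "upstream_es",
    "upstream_ee",
    "downstream_es",
    "downstream_ee",
]


@dataclass
class SeEventTable:
    """Skipped-exon events with per-sample inclusion/skipping junction counts.

    ``events`` holds one row per event with the EVENT_COLUMNS geometry;
    ``ijc``/``sjc`` are events x samples float matrices (NaN = missing
    replicate); ``inc_form_len``/``skip_form_len`` are per-event effective
    form lengths.
    """

    events: pd.DataFrame
    sample_ids: list
    ijc: np.ndarray
    sjc: np.ndarray
    inc_form_len: np.ndarray
    skip_form_len: np.ndarray
    genome_build: str = "unspecified"

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample ids")
        self.events = self.events.reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SpliceCorError(f"event table missing columns: {missing}")
        _check_unique(self.events["event_id"], "event ids")
        n_ev, n_s = len(self.events), len(self.sample_ids)
        self.ijc = np.asarray(self.ijc, dtype=float)
        self.sjc = np.asarray(self.sjc, dtype=float)
        self.inc_form_len = np.asarray(self.inc_form_len, dtype=float)
        self.skip_form_len = np.asarray(self.skip_form_len, dtype=float)
        for name, arr, shape in [
            ("ijc", self.ijc, (n_ev, n_s)),
            ("sjc", self.sjc, (n_ev, n_s)),
            ("inc_form_len", self.inc_form_len, (n_ev,)),
            ("skip_form_len", self.skip_form_len, (n_ev,)),
        ]:
            if arr.shape != shape:
                raise SpliceCorError(f"{name} shape {arr.shape} != {shape}")
        for name, arr in [("ijc", self.ijc), ("sjc", self.sjc)]:
            vals = arr[~np.isnan(arr)]
            if (vals < 0).any():
                raise SpliceCorError(f"negative junction count in {name}")
        if (self.inc_form_len < 1).any() or (self.skip_form_len < 1).any():
            raise SpliceCorError("effective form lengths must be >= 1")
        bad = self.events["exon_start"] >= self.events["exon_end"]
        if bad.any():
            raise SpliceCorError(
                f"exon_start >= exon_end for events {list(self.events.loc[bad, 'event_id'])[:5]}"
            )
        # NaN must appear in ijc and sjc together (a replicate is missing or not)
        if (np.isnan(self.ijc) != np.isnan(self.sjc)).any():
            warnings.warn("ijc/sjc missingness differs; treating cells missing in either as missing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_ids(self) -> list:
        return list(self.events["event_id"])


@dataclass
class PsiMatrix:
    """Events x samples inclusion levels in [0,1]; NaN where I+S = 0."""

    event_ids: list
    sample_ids: list
    psi: np.ndarray
    total_junction_reads: np.ndarray

    def __post_init__(self):
        self.event_ids = list(self.event_ids)
        self.sample_ids = list(self.sample_ids)
        self.psi = np.asarray(self.psi, dtype=float)
        self.total_junction_reads = np.asarray(self.total_junction_reads, dtype=float)
        shape = (len(self.event_ids), len(self.sample_ids))
        if self.psi.shape != shape or self.total_junction_reads.shape != shape:
            raise SpliceCorError("PSI matrix dimensions inconsistent")
        vals = self.psi[~np.isnan(self.psi)]
        if ((vals < 0) | (vals > 1)).any():
            raise SpliceCorError("PSI values outside [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.event_ids, columns=self.sample_ids)


@dataclass
class ActivityScoreVector:
    """One pathway-activity score per sample for a named gene set."""

    sample_ids: list
    geneset_name: str
    scores: np.ndarray
    n_genes_used: int

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise SpliceCorError("score vector length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise SpliceCorError("activity scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.geneset_name)


@dataclass
class NormalizedExpression:
    """log2(normalized count + 1) matrix with the size factors that produced it."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise SpliceCorError("expression matrix dimensions inconsistent")
        if self.size_factors.shape != (len(self.sample_ids),):
            raise SpliceCorError("one size factor per sample required")
        if (self.size_factors <= 0).any():
            raise SpliceCorError("size factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class OverlapResult:
    """Two-set overlap summary: Venn sizes, hypergeometric tail, Jaccard."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_hyper: float
    jaccard: float

    def __post_init__(self):
        if not (0 <= self.overlap <= min(self.size_a, self.size_b)):
            raise SpliceCorError("overlap larger than the smaller set")
        if not (0.0 <= self.jaccard <= 1.0):
            raise SpliceCorError("Jaccard index outside [0,1]")


@dataclass(frozen=True)
class GRun:
    """A maximal run of >=3 consecutive guanines on the sense strand."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def klass(self) -> str:
        return "G3" if self.length == 3 else "G4plus"


@dataclass(frozen=True)
class AsoTile:
    """One antisense oligo: reverse complement of a window slice."""

    tile_id: str
    start: int
    end: int
    sequence: str
    overlap_with_previous: int = 0

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise SpliceCorError(
                f"tile {self.tile_id}: sequence length {len(self.sequence)} != {self.end - self.start}"
            )


@dataclass(frozen=True)
class ElementCall:
    """Per-tile enhancer/silencer call from replicate PSI measurements.

    An ASO that significantly *increases* inclusion is blocking a silencer;
    one that *decreases* inclusion is blocking an enhancer.
    """

    tile_id: str
    mean_psi_treated: float
    mean_psi_ntc: float
    p_value: float
    direction: str  # increase | decrease | ns
    element_class: str  # silencer | enhancer | none
    p_adj: float = float("nan")
    direction_adj: str = "ns"
    element_class_adj: str = "none"

    def __post_init__(self):
        consistent = {
            ("increase", "silencer"),
            ("decrease", "enhancer"),
            ("ns", "none"),
        }
        if (self.direction, self.element_class) not in consistent:
            raise SpliceCorError(
                f"direction {self.direction!r} inconsistent with class {self.element_class!r}"
            )
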