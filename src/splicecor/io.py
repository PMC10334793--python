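"""Readers and writers for the external formats the pipeline touches.

All text I/O is UTF-8 and tab-separated; lines starting with ``#`` are
treated as comments and skipped. Genomic coordinates are kept 0-based
half-open throughout.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    EVENT_COLUMNS,
    CountsMatrix,
    FormatError,
    GeneSet,
    SampleMetadata,
    SeEventTable,
)
from .splicing import psi_from_junction_counts

__all__ = [
    "read_gmt",
    "read_se_table",
    "write_se_table",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_bed",
    "read_bed",
    "read_xlsx_events",
]

#: rMATS SE.MATS.JC.txt column dialect -> canonical names
_RMATS_GEOMETRY = {
    "ID": "event_id",
    "GeneID": "gene_id",
    "geneSymbol": "gene_symbol",
    "chr": "chrom",
    "strand": "strand",
    "exonStart_0base": "exon_start",
    "exonEnd": "exon_end",
    "upstreamES": "upstream_es",
    "upstreamEE": "upstream_ee",
    "downstreamES": "downstream_es",
    "downstreamEE": "downstream_ee",
}


def _open_text(path):
    return open(path, "r", encoding="utf-8")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kw)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in MSigDB GMT layout: name, description, genes...

    The description column is discarded. Duplicate genes on a line are
    collapsed with a warning; an empty gene list is a format error.
    """
    sets = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise FormatError(f"{path}: line {lineno}: gene set with no genes")
            name = fields[0]
            genes = [g for g in fields[2:] if g.strip()]
            if len(set(genes)) != len(genes):
                warnings.warn(f"{path}: line {lineno}: duplicate genes in set {name!r} collapsed")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def _split_counts(cell: str, n: int, what: str, row: int) -> np.ndarray:
    text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell)
    if n == 0:
        if text.strip() in ("", "nan"):
            return np.empty(0)
        raise FormatError(f"row {row}: {what} has counts but 0 samples were declared")
    parts = text.split(",")
    if len(parts) != n:
        raise FormatError(
            f"row {row}: {what} has {len(parts)} replicate counts, expected {n}"
        )
    out = np.empty(n, dtype=float)
    for i, p in enumerate(parts):
        p = p.strip()
        if p.upper() == "NA" or p == "":
            out[i] = np.nan
            continue
        try:
            v = int(p)
        except ValueError:
            raise FormatError(f"row {row}: malformed count {p!r} in {what}") from None
        if v < 0:
            raise FormatError(f"row {row}: negative count {v} in {what}")
        out[i] = v
    return out


def read_se_table(path, n_group1: int, n_group2: int, genome_build: str = "unspecified") -> SeEventTable:
    """Read a skipped-exon table in the rMATS JC dialect.

    Replicate counts (comma-separated in IJC_SAMPLE_1 / SJC_SAMPLE_1 /
    IJC_SAMPLE_2 / SJC_SAMPLE_2, ``NA`` allowed) are split into per-sample
    columns named ``G1_S<i>`` / ``G2_S<i>``. If IncLevel columns are
    present, PSI is re-derived from the counts and compared within
    +/-0.001 (rMATS rounds to 3 decimals); on mismatch a warning is
    emitted and the derived value wins — counts are the source of truth.
    """
    df = _read_tsv(path, dtype=str)
    required = list(_RMATS_GEOMETRY) + [
        "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
        "IncFormLen", "SkipFormLen",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing rMATS columns: {missing}")

    n_s = n_group1 + n_group2
    ijc = np.empty((len(df), n_s))
    sjc = np.empty((len(df), n_s))
    for r in range(len(df)):
        ijc[r, :n_group1] = _split_counts(df.loc[r, "IJC_SAMPLE_1"], n_group1, "IJC_SAMPLE_1", r)
        sjc[r, :n_group1] = _split_counts(df.loc[r, "SJC_SAMPLE_1"], n_group1, "SJC_SAMPLE_1", r)
        ijc[r, n_group1:] = _split_counts(df.loc[r, "IJC_SAMPLE_2"], n_group2, "IJC_SAMPLE_2", r)
        sjc[r, n_group1:] = _split_counts(df.loc[r, "SJC_SAMPLE_2"], n_group2, "SJC_SAMPLE_2", r)

    events = pd.DataFrame({new: df[old] for old, new in _RMATS_GEOMETRY.items()})
    for col in ["exon_start", "exon_end", "upstream_es", "upstream_ee", "downstream_es", "downstream_ee"]:
        events[col] = events[col].astype(np.int64)
    lI = df["IncFormLen"].astype(float).to_numpy()
    lS = df["SkipFormLen"].astype(float).to_numpy()

    sample_ids = [f"G1_S{i+1}" for i in range(n_group1)] + [f"G2_S{i+1}" for i in range(n_group2)]
    table = SeEventTable(events, sample_ids, ijc, sjc, lI, lS, genome_build=genome_build)

    # IncLevel consistency check: rMATS rounds PSI to 3 decimals
    for col, sl in [("IncLevel1", slice(0, n_group1)), ("IncLevel2", slice(n_group1, n_s))]:
        if col not in df.columns:
            continue
        for r in range(len(df)):
            stated = [np.nan if p.strip().upper() == "NA" else float(p)
                      for p in str(df.loc[r, col]).split(",")]
            derived = [psi_from_junction_counts(i, s, lI[r], lS[r])
                       for i, s in zip(ijc[r, sl], sjc[r, sl])]
            for st, de in zip(stated, derived):
                if np.isnan(st) and np.isnan(de):
                    continue
                if np.isnan(st) != np.isnan(de) or abs(st - de) > 1e-3:
                    warnings.warn(
                        f"{path}: row {r}: {col} {st} disagrees with count-derived PSI "
                        f"{de:.4f}; using the derived value"
                    )
                    break
    return table


def write_se_table(table: SeEventTable, path, n_group1: int | None = None) -> None:
    """Write a SeEventTable back to the rMATS JC dialect.

    ``n_group1`` defaults to the number of samples whose id starts with
    ``G1_`` (the read_se_table convention), else all samples go in group 1.
    """
    if n_group1 is None:
        g1 = [s for s in table.sample_ids if str(s).startswith("G1_")]
        n_group1 = len(g1) if g1 else len(table.sample_ids)

    def join(arr_row):
        return ",".join("NA" if np.isnan(v) else str(int(v)) for v in arr_row)

    inv = {v: k for k, v in _RMATS_GEOMETRY.items()}
    out = pd.DataFrame({inv[c]: table.events[c] for c in inv if c in table.events.columns})
    out["IJC_SAMPLE_1"] = [join(r) for r in table.ijc[:, :n_group1]]
    out["SJC_SAMPLE_1"] = [join(r) for r in table.sjc[:, :n_group1]]
    out["IJC_SAMPLE_2"] = [join(r) for r in table.ijc[:, n_group1:]]
    out["SJC_SAMPLE_2"] = [join(r) for r in table.sjc[:, n_group1:]]
    out["IncFormLen"] = table.inc_form_len.astype(int)
    out["SkipFormLen"] = table.skip_form_len.astype(int)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_counts(path) -> CountsMatrix:
    """Read a genes x samples TSV of integer read counts (header = sample ids)."""
    df = _read_tsv(path, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr.astype(float))) or np.any(arr.astype(float) % 1 != 0):
            bad = df.columns[np.where((df.to_numpy().astype(float) % 1 != 0).any(axis=0))[0]]
            raise FormatError(f"{path}: non-integer count cells in columns {list(bad)}")
        arr = arr.astype(np.int64)
    return CountsMatrix(list(df.index), list(df.columns), arr)


def write_counts(counts: CountsMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", encoding="utf-8")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV with sample_id, cohort and stage/condition columns."""
    return SampleMetadata(_read_tsv(path, dtype=str))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id", encoding="utf-8")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; sequences upper-cased, U -> T."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def write_bed(intervals, path) -> None:
    """Write 6-column BED (chrom, start, end, name, score, strand), input order kept."""
    lines = []
    for chrom, start, end, name, score, strand in intervals:
        if start >= end:
            raise FormatError(f"BED interval {name!r}: start {start} >= end {end}")
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_bed(path) -> list[tuple]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c, s, e, n, sc, st = line.split("\t")[:6]
            out.append((c, int(s), int(e), n, sc, st))
    return out


def read_xlsx_events(path, sheet=None) -> dict[str, pd.DataFrame]:
    """Permissive reader for supplementary XLSX event lists.

    Each sheet is one comparison. Columns are matched by name against the
    rMATS dialect keys (case-insensitive); recognized geometry columns are
    renamed to the canonical names, everything else is kept as-is.
    """
    book = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if isinstance(book, pd.DataFrame):
        book = {sheet or "sheet1": book}
    lower = {k.lower(): v for k, v in _RMATS_GEOMETRY.items()}
    out = {}
    for name, df in book.items():
        renames = {c: lower[c.strip().lower()] for c in df.columns if c.strip().lower() in lower}
        out[name] = df.rename(columns=renames)
    return out
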