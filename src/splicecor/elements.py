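"""Cis-element mapping: G-run scanning, ASO tile design, and enhancer/silencer
calls from replicate PSI measurements.

G-runs — stretches of three or more consecutive guanines, the binding
motif of hnRNP H/F — are scanned as *maximal* runs on the sense
(pre-mRNA) strand and classed G3 (length exactly 3) or G4plus (>= 4).
An antisense-oligo tiling panel walks fixed-length tiles (default 18 nt)
across a window spanning an exon and its intronic flanks; each tile is
the reverse complement of its window slice. Comparing exon PSI under
each ASO with a nontargeting control (NTC) classifies the blocked
element: a significant PSI increase means the ASO blocked a silencer, a
decrease means it blocked an enhancer.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .correlate import bh_adjust
from .datatypes import AsoTile, ElementCall, GRun, SpliceCorError

__all__ = [
    "find_g_runs",
    "design_tiles",
    "classify_aso_effect",
    "classify_aso_panel",
    "genomic_interval",
    "local_interval",
    "build_element_map",
]

_VALID = set("ACGT")


def find_g_runs(sequence: str, min_len: int = 3) -> list[GRun]:
    """All maximal runs of consecutive G with length >= min_len, ascending by start."""
    sequence = sequence.upper()
    for pos, base in enumerate(sequence):
        if base not in _VALID:
            raise SpliceCorError(f"non-ACGT character {base!r} at position {pos}")
    runs = []
    i, n = 0, len(sequence)
    while i < n:
        if sequence[i] == "G":
            j = i
            while j < n and sequence[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append(GRun(i, j))
            i = j
        else:
            i += 1
    return runs


def design_tiles(window, tile_len: int = 18, schedule=None, prefix: str = "T") -> list[AsoTile]:
    """Design an ASO tiling panel over a sense-strand window sequence.

    Without a schedule, abutting tiles are placed at step ``tile_len``
    from position 0; a trailing stretch shorter than ``tile_len`` is left
    uncovered (its length is available as ``window_length - tiles[-1].end``).
    With a schedule (a list of start offsets), one tile is placed per
    offset and ``overlap_with_previous`` records how far it reaches into
    the previous tile.

    ``window`` may be a sequence string (tile sequences become reverse
    complements of the corresponding slice) or an integer length (tile
    geometry only, sequences filled with N).
    """
    if isinstance(window, int):
        length, seq = window, "N" * window
    else:
        seq = str(window).upper()
        length = len(seq)
    if tile_len > length:
        raise SpliceCorError(f"tile length {tile_len} exceeds window length {length}")
    if schedule is None:
        offsets = list(range(0, length - tile_len + 1, tile_len))
    else:
        offsets = list(schedule)
        for off in offsets:
            if off < 0 or off + tile_len > length:
                raise SpliceCorError(f"tile offset {off} + {tile_len} exceeds window {length}")
    tiles = []
    prev_end = None
    for i, off in enumerate(offsets):
        end = off + tile_len
        aso = str(Seq(seq[off:end]).reverse_complement())
        overlap = max(0, prev_end - off) if prev_end is not None else 0
        tiles.append(AsoTile(f"{prefix}{i + 1:02d}", off, end, aso, overlap))
        prev_end = end
    return tiles


def _call(tile_id, treated, ntc, p, alpha):
    mt, mn = float(np.mean(treated)), float(np.mean(ntc))
    if p < alpha and mt > mn:
        direction, klass = "increase", "silencer"
    elif p < alpha and mt < mn:
        direction, klass = "decrease", "enhancer"
    else:
        direction, klass = "ns", "none"
    return mt, mn, direction, klass


def classify_aso_effect(
    psi_treated_reps,
    psi_ntc_reps,
    alpha: float = 0.05,
    tile_id: str = "tile",
    welch: bool = False,
) -> ElementCall:
    """Two-sided t-test of treated vs NTC replicate PSI; call the blocked element.

    Equal-variance (Student) t-test by default; Welch via ``welch=True``.
    Significant increase in inclusion -> the ASO blocked a silencer;
    significant decrease -> an enhancer; otherwise no call.
    """
    treated = np.asarray(psi_treated_reps, dtype=float)
    ntc = np.asarray(psi_ntc_reps, dtype=float)
    if treated.size < 2 or ntc.size < 2:
        raise SpliceCorError("need >= 2 replicates per arm")
    res = stats.ttest_ind(treated, ntc, equal_var=not welch)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    mt, mn, direction, klass = _call(tile_id, treated, ntc, p, alpha)
    return ElementCall(tile_id, mt, mn, p, direction, klass)


def classify_aso_panel(
    panel_psi: dict,
    ntc_reps,
    alpha: float = 0.05,
    welch: bool = False,
) -> list[ElementCall]:
    """Classify every tile of a panel against the shared NTC arm.

    Per-tile raw-alpha calls (matching per-ASO significance stars) are
    reported alongside BH-adjusted calls across the panel.
    """
    tile_ids = list(panel_psi)
    raw = [classify_aso_effect(panel_psi[t], ntc_reps, alpha, tile_id=t, welch=welch)
           for t in tile_ids]
    p_adj = bh_adjust([c.p_value for c in raw])
    out = []
    for c, pa in zip(raw, p_adj):
        _, _, d_adj, k_adj = _call(c.tile_id, [c.mean_psi_treated], [c.mean_psi_ntc], pa, alpha)
        out.append(ElementCall(c.tile_id, c.mean_psi_treated, c.mean_psi_ntc,
                               c.p_value, c.direction, c.element_class,
                               p_adj=float(pa), direction_adj=d_adj, element_class_adj=k_adj))
    return out


def genomic_interval(local_start: int, local_end: int, window_origin: int,
                     window_length: int, strand: str) -> tuple[int, int]:
    """Map a local window interval (0-based half-open) to genomic coordinates.

    ``window_origin`` is the genomic coordinate of the window's leftmost
    reference base. On the minus strand, local position 0 is the window's
    rightmost reference base, so intervals mirror-map.
    """
    if strand == "+":
        return window_origin + local_start, window_origin + local_end
    if strand == "-":
        return (window_origin + window_length - local_end,
                window_origin + window_length - local_start)
    raise SpliceCorError(f"strand must be '+' or '-', got {strand!r}")


def local_interval(genomic_start: int, genomic_end: int, window_origin: int,
                   window_length: int, strand: str) -> tuple[int, int]:
    """Inverse of genomic_interval."""
    if strand == "+":
        return genomic_start - window_origin, genomic_end - window_origin
    if strand == "-":
        return (window_origin + window_length - genomic_end,
                window_origin + window_length - genomic_start)
    raise SpliceCorError(f"strand must be '+' or '-', got {strand!r}")


#: BED score per element class, so browsers can shade calls
_CLASS_SCORE = {"enhancer": 1000, "silencer": 500, "none": 0}


def build_element_map(
    tiles: list[AsoTile],
    calls: list[ElementCall],
    g_runs: list[GRun],
    window_origin: int,
    window_length: int,
    chrom: str = "chr?",
    strand: str = "+",
) -> list[tuple]:
    """BED-ready intervals for a tiling panel: one per tile (named
    ``<tile_id>|<element_class>``) plus one per G-run (named by class).

    Local window offsets are lifted to genomic coordinates through
    ``genomic_interval`` (strand-aware).
    """
    by_id = {t.tile_id: t for t in tiles}
    intervals = []
    for call in calls:
        if call.tile_id not in by_id:
            raise SpliceCorError(f"call references unknown tile {call.tile_id!r}")
        t = by_id[call.tile_id]
        gs, ge = genomic_interval(t.start, t.end, window_origin, window_length, strand)
        intervals.append((chrom, gs, ge, f"{t.tile_id}|{call.element_class}",
                          _CLASS_SCORE[call.element_class], strand))
    for run in g_runs:
        gs, ge = genomic_interval(run.start, run.end, window_origin, window_length, strand)
        intervals.append((chrom, gs, ge, run.klass, 0, strand))
    return intervals
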