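"""PSI quantification from junction counts and two-group differential splicing.

The inclusion level of a cassette exon is estimated from junction reads as
the length-normalized ratio

    psi = (I / lI) / (I / lI + S / lS)

where I and S are inclusion- and skipping-junction read counts and lI, lS
the effective lengths of the two isoform forms. A read is an inclusion
read with probability q(psi) = psi*lI / (psi*lI + (1-psi)*lS), which is the
binomial model used by the two-group likelihood-ratio test below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PsiMatrix, SampleMetadata, SeEventTable, SpliceCorError
from .correlate import bh_adjust

__all__ = [
    "psi_from_junction_counts",
    "psi_from_band_intensities",
    "build_psi_matrix",
    "differential_splicing_test",
    "filter_significant_events",
]


def psi_from_junction_counts(ijc: float, sjc: float, inc_form_len: float, skip_form_len: float) -> float:
    """Length-normalized inclusion level; NaN when no junction reads.

    >>> psi_from_junction_counts(30, 10, 2, 1)
    0.6
    """
    if np.isnan(ijc) or np.isnan(sjc):
        return float("nan")
    if ijc < 0 or sjc < 0:
        raise SpliceCorError("junction counts must be non-negative")
    if inc_form_len < 1 or skip_form_len < 1:
        raise SpliceCorError("effective form lengths must be >= 1")
    if ijc + sjc == 0:
        return float("nan")
    a = ijc / inc_form_len
    b = sjc / skip_form_len
    return a / (a + b)


def psi_from_band_intensities(inclusion_intensity: float, skip_intensity: float) -> float:
    """Percent spliced in from RT-PCR band intensities, on the 0-100 scale."""
    if inclusion_intensity < 0 or skip_intensity < 0:
        raise SpliceCorError("band intensities must be non-negative")
    total = inclusion_intensity + skip_intensity
    if total == 0:
        raise SpliceCorError("both band intensities are zero")
    return 100.0 * inclusion_intensity / total


def build_psi_matrix(table: SeEventTable) -> PsiMatrix:
    """Elementwise PSI over an event table; records total junction reads."""
    lI = table.inc_form_len[:, None]
    lS = table.skip_form_len[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = table.ijc / lI
        b = table.sjc / lS
        psi = np.where(a + b > 0, a / (a + b), np.nan)
    total = table.ijc + table.sjc
    psi = np.where(np.isnan(total), np.nan, psi)
    return PsiMatrix(table.event_ids, table.sample_ids, psi, total)


def _binom_loglik(I: float, S: float, q: float) -> float:
    # binomial log-likelihood up to the data-only constant, safe at q in {0,1}
    ll = 0.0
    if I > 0:
        ll += I * np.log(q) if q > 0 else -np.inf
    if S > 0:
        ll += S * np.log1p(-q) if q < 1 else -np.inf
    return ll


def _q_of_psi(psi: float, lI: float, lS: float) -> float:
    return psi * lI / (psi * lI + (1 - psi) * lS)


def _lrt_pooled(I1, S1, I2, S2, lI, lS):
    """1-df LRT of H0: psi1 == psi2 under the binomial junction-read model.

    The MLE of q is the observed inclusion-read fraction, and q <-> psi is
    a monotone bijection, so the alternative maximizes at q_g = I_g/(I_g+S_g)
    and the null at the pooled fraction.
    """
    q1 = I1 / (I1 + S1)
    q2 = I2 / (I2 + S2)
    q0 = (I1 + I2) / (I1 + S1 + I2 + S2)
    ll_alt = _binom_loglik(I1, S1, q1) + _binom_loglik(I2, S2, q2)
    ll_null = _binom_loglik(I1, S1, q0) + _binom_loglik(I2, S2, q0)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return stat, float(stats.chi2.sf(stat, df=1))


def differential_splicing_test(
    table: SeEventTable,
    groups: SampleMetadata,
    group_col: str = "condition",
) -> pd.DataFrame:
    """Per-event two-group differential splicing, replicates pooled within group.

    Junction counts are summed within each group (missing replicates
    dropped), group PSI estimated by the length-normalized formula, and a
    1-df binomial likelihood-ratio test of equal PSI computed per event.
    BH adjustment runs across all tested events; events where either group
    has zero total reads are returned untested (``tested = False``).

    Returns a DataFrame with columns event_id, psi_group1, psi_group2,
    delta_psi, mean_junction_reads, lrt_stat, p_value, fdr, tested.
    """
    labels = groups.group_labels(group_col)
    shared = [s for s in table.sample_ids if s in labels.index]
    if not shared:
        raise SpliceCorError("no shared samples between event table and metadata")
    labels = labels.loc[shared]
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise SpliceCorError(f"need exactly two groups, got {uniq}")
    col_idx = [table.sample_ids.index(s) for s in shared]
    mask1 = np.array([labels[s] == uniq[0] for s in shared])
    if mask1.all() or not mask1.any():
        raise SpliceCorError("one group is empty")

    ijc = table.ijc[:, col_idx]
    sjc = table.sjc[:, col_idx]
    I1 = np.nansum(ijc[:, mask1], axis=1)
    S1 = np.nansum(sjc[:, mask1], axis=1)
    I2 = np.nansum(ijc[:, ~mask1], axis=1)
    S2 = np.nansum(sjc[:, ~mask1], axis=1)
    mean_reads = np.nanmean(ijc + sjc, axis=1)

    rows = []
    for e in range(table.n_events):
        lI, lS = table.inc_form_len[e], table.skip_form_len[e]
        t1, t2 = I1[e] + S1[e], I2[e] + S2[e]
        if t1 == 0 or t2 == 0:
            rows.append((table.event_ids[e], np.nan, np.nan, np.nan,
                         mean_reads[e], np.nan, np.nan, False))
            continue
        p1 = psi_from_junction_counts(I1[e], S1[e], lI, lS)
        p2 = psi_from_junction_counts(I2[e], S2[e], lI, lS)
        stat, p = _lrt_pooled(I1[e], S1[e], I2[e], S2[e], lI, lS)
        rows.append((table.event_ids[e], p1, p2, p1 - p2, mean_reads[e], stat, p, True))

    df = pd.DataFrame(
        rows,
        columns=["event_id", "psi_group1", "psi_group2", "delta_psi",
                 "mean_junction_reads", "lrt_stat", "p_value", "tested"],
    )
    df["fdr"] = np.nan
    tested = df["tested"].to_numpy()
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    df.attrs["group1"], df.attrs["group2"] = uniq
    return df


def filter_significant_events(
    records: pd.DataFrame,
    min_reads: float = 10,
    min_abs_dpsi: float = 0.05,
    max_fdr: float = 0.05,
    reads_statistic: str = "mean",
) -> set:
    """Significant-event filter: reads > min_reads, |dPSI| > min_abs_dpsi, FDR < max_fdr.

    All three comparisons are strict. ``reads_statistic`` selects which
    per-event read summary the records carry ('mean' is the default
    interpretation of junction reads per event; 'min'/'sum' columns are
    honored when present).
    """
    col = {"mean": "mean_junction_reads",
           "min": "min_junction_reads",
           "sum": "sum_junction_reads"}[reads_statistic]
    if col not in records.columns:
        raise SpliceCorError(f"records lack column {col!r}")
    keep = (
        records["tested"]
        & (records[col] > min_reads)
        & (records["delta_psi"].abs() > min_abs_dpsi)
        & (records["fdr"] < max_fdr)
    )
    return set(records.loc[keep, "event_id"])
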