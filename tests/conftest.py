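import numpy as np
import pandas as pd
import pytest

from splicecor.datatypes import CountsMatrix, SampleMetadata, SeEventTable


@pytest.fixture
def tiny_counts():
    # the 3-gene x 2-sample median-of-ratios worked example
    return CountsMatrix(
        ["g1", "g2", "g3"], ["A", "B"], np.array([[10, 20], [100, 200], [4, 8]])
    )


@pytest.fixture
def two_group_meta():
    return SampleMetadata(pd.DataFrame(
        {"cohort": "EXP",
         "condition": ["control", "control", "ko", "ko"]},
        index=pd.Index(["G1_S1", "G1_S2", "G2_S1", "G2_S2"], name="sample_id"),
    ))


def make_se_table(ijc, sjc, lI=1.0, lS=1.0, sample_ids=None, genome_build="synthetic"):
    """Hand-built SeEventTable with trivially valid geometry."""
    ijc = np.asarray(ijc, dtype=float)
    n_ev, n_s = ijc.shape
    if sample_ids is None:
        sample_ids = [f"G1_S{i+1}" for i in range(n_s // 2)] + \
                     [f"G2_S{i+1}" for i in range(n_s - n_s // 2)]
    start = 100 + 1000 * np.arange(n_ev)
    events = pd.DataFrame({
        "event_id": [f"E{i}" for i in range(n_ev)],
        "gene_id": [f"g{i}" for i in range(n_ev)],
        "gene_symbol": [f"Sym{i}" for i in range(n_ev)],
        "chrom": "chr1",
        "strand": "+",
        "exon_start": start,
        "exon_end": start + 82,
        "upstream_es": start - 200,
        "upstream_ee": start - 100,
        "downstream_es": start + 182,
        "downstream_ee": start + 282,
    })
    return SeEventTable(
        events, sample_ids, ijc, np.asarray(sjc, dtype=float),
        np.full(n_ev, float(lI)), np.full(n_ev, float(lS)),
        genome_build=genome_build,
    )


@pytest.fixture
def se_table_factory():
    return make_se_table
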