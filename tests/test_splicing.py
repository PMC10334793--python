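import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecor import (
    SpliceCorError,
    build_psi_matrix,
    differential_splicing_test,
    filter_significant_events,
    psi_from_band_intensities,
    psi_from_junction_counts,
    read_se_table,
)
from splicecor.splicing import _lrt_pooled


class TestPsiFormula:
    @pytest.mark.parametrize(
        "I,S,lI,lS,expected",
        [
            (0, 5, 1, 1, 0.0),
            (7, 7, 3, 3, 0.5),  # I=S, lI=lS -> symmetry
            (30, 10, 2, 1, 0.6),  # length-normalized: 15/(15+10)
            (5, 0, 1, 1, 1.0),
        ],
    )
    def test_worked_values(self, I, S, lI, lS, expected):
        assert psi_from_junction_counts(I, S, lI, lS) == pytest.approx(expected)

    def test_no_reads_is_missing(self):
        assert np.isnan(psi_from_junction_counts(0, 0, 100, 50))

    def test_negative_input_rejected(self):
        with pytest.raises(SpliceCorError):
            psi_from_junction_counts(-1, 5, 1, 1)

    @given(I=st.integers(0, 500), S=st.integers(0, 500), c=st.integers(1, 9),
           lI=st.integers(1, 300), lS=st.integers(1, 300))
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_count_scaling(self, I, S, c, lI, lS):
        p1 = psi_from_junction_counts(I, S, lI, lS)
        p2 = psi_from_junction_counts(c * I, c * S, lI, lS)
        assert (np.isnan(p1) and np.isnan(p2)) or p1 == pytest.approx(p2)


class TestBandIntensities:
    @pytest.mark.parametrize("incl,skip,expected", [
        (0, 10, 0.0),
        (1, 1, 50.0),
        (18.9, 81.1, 18.9),  # minigene-style readout: percent scale
    ])
    def test_percent_definition(self, incl, skip, expected):
        assert psi_from_band_intensities(incl, skip) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(SpliceCorError):
            psi_from_band_intensities(0, 0)


class TestPsiMatrix:
    def test_shape_and_missing_cells(self, se_table_factory):
        ijc = [[3, 0, 2, 1], [0, 0, 5, 5], [1, 1, 1, 1]]
        sjc = [[1, 0, 2, 3], [0, 0, 5, 5], [0, 0, 0, 0]]
        pm = build_psi_matrix(se_table_factory(ijc, sjc))
        assert pm.psi.shape == (3, 4)
        assert np.isnan(pm.psi[0, 1]) and np.isnan(pm.psi[1, 0])
        assert pm.psi[2, 0] == 1.0
        assert pm.total_junction_reads[0, 0] == 4

    def test_matches_inclevel_of_rmats_dialect_fixture(self, tmp_path):
        # IncLevel values computed independently from the formula, rounded
        # to 3 decimals the way rMATS prints them
        header = ("ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
                  "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
                  "IJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\t"
                  "IncFormLen\tSkipFormLen\tIncLevel1\tIncLevel2")
        # event 1: I/lI=30/198, S/lS=10/99 -> psi=0.6; I=50,S=50 -> 0.333
        rows = [
            "1\tG1\tS1\tchr1\t+\t100\t182\t10\t50\t300\t400\t"
            "30,60\t10,20\t50\t50\t198\t99\t0.6,0.6\t0.333",
            "2\tG2\tS2\tchr1\t-\t900\t982\t700\t800\t1100\t1200\t"
            "0,NA\t5,NA\t10\t0\t198\t99\t0.0,NA\t1.0",
        ]
        p = tmp_path / "se.txt"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        t = read_se_table(p, 2, 1)  # no mismatch warnings expected
        pm = build_psi_matrix(t)
        np.testing.assert_allclose(pm.psi[0], [0.6, 0.6, 1 / 3], atol=1e-3)
        assert pm.psi[1, 0] == 0.0 and np.isnan(pm.psi[1, 1]) and pm.psi[1, 2] == 1.0


class TestLrt:
    def test_identical_pooled_counts_give_p_one(self, se_table_factory, two_group_meta):
        t = se_table_factory([[20, 20, 20, 20]], [[30, 30, 30, 30]])
        rec = differential_splicing_test(t, two_group_meta)
        assert rec.loc[0, "delta_psi"] == 0.0
        assert rec.loc[0, "p_value"] == pytest.approx(1.0)
        assert rec.loc[0, "lrt_stat"] == pytest.approx(0.0, abs=1e-9)

    def test_extreme_separation(self, se_table_factory, two_group_meta):
        t = se_table_factory([[500, 500, 0, 0]], [[0, 0, 500, 500]])
        rec = differential_splicing_test(t, two_group_meta)
        assert rec.loc[0, "delta_psi"] == pytest.approx(1.0)
        assert rec.loc[0, "p_value"] < 1e-100

    def test_worked_example_30_70_vs_50_50(self):
        # brute-force verified: grid maximization of the binomial likelihood
        # gives 8.4024 (the closed-form MLE psi = I/(I+S) when lI = lS)
        stat, p = _lrt_pooled(30, 70, 50, 50, 1, 1)
        assert stat == pytest.approx(8.402370, abs=1e-4)
        assert p == pytest.approx(0.0037473, rel=1e-3)

    def test_matches_brute_force_grid_on_random_tables(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(1e-6, 1 - 1e-6, 200001)
        for _ in range(10):
            I1, S1, I2, S2 = rng.integers(1, 200, size=4)
            stat, _ = _lrt_pooled(I1, S1, I2, S2, 1, 1)
            def ll(I, S, p):
                return I * np.log(p) + S * np.log1p(-p)
            alt = ll(I1, S1, grid).max() + ll(I2, S2, grid).max()
            null = (ll(I1, S1, grid) + ll(I2, S2, grid)).max()
            assert stat == pytest.approx(2 * (alt - null), abs=1e-6)

    def test_zero_read_group_skipped_and_reported(self, se_table_factory, two_group_meta):
        t = se_table_factory([[0, 0, 5, 5], [3, 3, 3, 3]], [[0, 0, 5, 5], [1, 1, 1, 1]])
        rec = differential_splicing_test(t, two_group_meta)
        assert not rec.loc[0, "tested"] and rec.loc[1, "tested"]
        assert np.isnan(rec.loc[0, "fdr"])

    def test_na_replicates_dropped_from_pooling(self, se_table_factory, two_group_meta):
        withna = se_table_factory([[10, np.nan, 20, 20]], [[10, np.nan, 20, 20]])
        nona = se_table_factory([[10, 0, 20, 20]], [[10, 0, 20, 20]])
        r1 = differential_splicing_test(withna, two_group_meta)
        r2 = differential_splicing_test(nona, two_group_meta)
        assert r1.loc[0, "lrt_stat"] == pytest.approx(r2.loc[0, "lrt_stat"])

    def test_one_group_missing_rejected(self, se_table_factory, two_group_meta):
        t = se_table_factory([[1, 1]], [[1, 1]], sample_ids=["G1_S1", "G1_S2"])
        meta = two_group_meta
        with pytest.raises(SpliceCorError):
            differential_splicing_test(t, meta)


class TestFilters:
    def _records(self, **kw):
        base = dict(event_id="E", psi_group1=0.5, psi_group2=0.2, delta_psi=0.3,
                    mean_junction_reads=50.0, lrt_stat=20.0, p_value=1e-5,
                    fdr=1e-4, tested=True)
        base.update(kw)
        return pd.DataFrame([base])

    def test_strict_boundaries_excluded(self):
        assert filter_significant_events(self._records(mean_junction_reads=10.0)) == set()
        assert filter_significant_events(self._records(delta_psi=0.05)) == set()
        assert filter_significant_events(self._records(delta_psi=-0.049)) == set()
        assert filter_significant_events(self._records(fdr=0.05)) == set()

    def test_passing_event_included(self):
        assert filter_significant_events(
            self._records(delta_psi=-0.30, fdr=1e-4, mean_junction_reads=50)) == {"E"}

    def test_untested_events_never_pass(self):
        assert filter_significant_events(self._records(tested=False)) == set()
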