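import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecor import (
    ActivityScoreVector,
    PsiMatrix,
    SampleMetadata,
    SpliceCorError,
    bh_adjust,
    correlate_expression_with_activity,
    correlate_psi_with_activity,
    pearson_r_p,
    permutation_pvalue,
)
from splicecor.datatypes import NormalizedExpression


def bh_oracle(p):
    """Direct step-up: adj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(((m / np.arange(m, 0, -1)) * p[order][::-1]))[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.arange(1, 6, dtype=float)
        r, p = pearson_r_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(1, 6, dtype=float)
        r, _ = pearson_r_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_worked_example(self):
        # hand covariance/variance: r = 0.8, t-tail p = 0.1041
        r, p = pearson_r_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(0.10409, abs=1e-4)

    def test_zero_variance_flagged_not_raised(self):
        r, p = pearson_r_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_pairwise_deletion_of_missing(self):
        r_full, _ = pearson_r_p([1, 2, 3, 4], [2, 4, 6, 8])
        r_nan, _ = pearson_r_p([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 0])
        assert r_nan == pytest.approx(r_full)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True),
           st.floats(0.1, 5.0), st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_positive_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(42)
        x = np.array(xs)
        y = rng.permutation(x)
        if np.ptp(y) == 0:
            return
        r1, p1 = pearson_r_p(x, y)
        r2, p2 = pearson_r_p(y, x)
        r3, p3 = pearson_r_p(a * x + b, y)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
        assert r1 == pytest.approx(r3, abs=1e-9)


class TestBh:
    def test_single_and_tied_inputs_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(SpliceCorError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_bounds(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


def _meta(samples, cohorts):
    return SampleMetadata(pd.DataFrame(
        {"cohort": cohorts, "stage": "tumor"},
        index=pd.Index(samples, name="sample_id")))


class TestCorrelatePsi:
    def test_per_cohort_bh_differs_from_pooled(self):
        # crafted so pooling would change the adjusted values
        samples = [f"s{i}" for i in range(24)]
        cohorts = ["C1"] * 12 + ["C2"] * 12
        rng = np.random.default_rng(3)
        score = np.concatenate([np.linspace(-1, 1, 12)] * 2)
        psi = np.clip(rng.uniform(0.2, 0.8, size=(4, 24)), 0, 1)
        psi[0, :12] = np.clip(0.5 - 0.2 * score[:12] + rng.normal(0, 0.01, 12), 0, 1)
        pm = PsiMatrix([f"E{i}" for i in range(4)], samples, psi,
                       np.full((4, 24), 100.0))
        sv = ActivityScoreVector(samples, "PWY", score, 4)
        rec = correlate_psi_with_activity(pm, sv, _meta(samples, cohorts), min_n=5)
        assert set(rec["cohort"]) == {"C1", "C2"}
        for cohort, sub in rec.groupby("cohort"):
            ok = sub["evaluable"]
            np.testing.assert_allclose(sub.loc[ok, "p_adj"],
                                       bh_oracle(sub.loc[ok, "p_value"].to_numpy()))
        pooled = bh_oracle(rec.loc[rec["evaluable"], "p_value"].to_numpy())
        assert not np.allclose(pooled, rec.loc[rec["evaluable"], "p_adj"])

    def test_constant_psi_event_flagged_unevaluable(self):
        samples = [f"s{i}" for i in range(12)]
        psi = np.vstack([np.full(12, 0.5), np.linspace(0.1, 0.9, 12)])
        pm = PsiMatrix(["const", "var"], samples, psi, np.full((2, 12), 50.0))
        sv = ActivityScoreVector(samples, "PWY", np.linspace(-1, 1, 12), 4)
        rec = correlate_psi_with_activity(pm, sv, _meta(samples, ["C"] * 12), min_n=5)
        const = rec[rec.target_id == "const"].iloc[0]
        assert not const["evaluable"] and np.isnan(const["p_adj"])

    def test_low_n_reports_r_but_withholds_p(self):
        samples = [f"s{i}" for i in range(6)]
        pm = PsiMatrix(["e"], samples, np.linspace(0.2, 0.8, 6)[None, :],
                       np.full((1, 6), 50.0))
        sv = ActivityScoreVector(samples, "PWY", np.linspace(-1, 1, 6), 4)
        rec = correlate_psi_with_activity(pm, sv, _meta(samples, ["C"] * 6), min_n=10)
        row = rec.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert not row["evaluable"] and np.isnan(row["p_value"])

    def test_no_shared_samples_rejected(self):
        pm = PsiMatrix(["e"], ["a", "b", "c"], np.zeros((1, 3)), np.ones((1, 3)))
        sv = ActivityScoreVector(["x", "y", "z"], "PWY", np.zeros(3), 4)
        with pytest.raises(SpliceCorError):
            correlate_psi_with_activity(pm, sv, _meta(["x", "y", "z"], ["C"] * 3))


class TestCorrelateExpression:
    def test_gene_equal_and_negated_score(self):
        samples = [f"s{i}" for i in range(12)]
        score = np.linspace(-2, 2, 12)
        expr = NormalizedExpression(["up", "down"], samples,
                                    np.vstack([score, -score]), np.ones(12))
        sv = ActivityScoreVector(samples, "PWY", score, 4)
        rec = correlate_expression_with_activity(expr, ["up", "down"], sv,
                                                 _meta(samples, ["C"] * 12))
        assert rec.set_index("target_id").loc["up", "r"] == pytest.approx(1.0)
        assert rec.set_index("target_id").loc["down", "r"] == pytest.approx(-1.0)


class TestPermutation:
    def test_extreme_observed_r_gives_minimal_p(self):
        x = np.linspace(0, 1, 30)
        y = 2 * x
        assert permutation_pvalue(x, y, B=199, seed=0) == pytest.approx(1 / 200)

    def test_same_seed_same_p(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert permutation_pvalue(x, y, B=200, seed=11) == \
               permutation_pvalue(x, y, B=200, seed=11)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = [permutation_pvalue(rng.normal(size=20), rng.normal(size=20),
                                 B=199, seed=i) for i in range(60)]
        # under independence ~half the p-values land below 0.5
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8

    def test_small_b_rejected(self):
        with pytest.raises(SpliceCorError):
            permutation_pvalue([1, 2, 3], [3, 2, 1], B=10)
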