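"""Integrated permutation DE test: grouping, statistics, empirical p-values,
Stouffer combination, Storey q and DEG calling, against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

from sigloss import (DegCriteria, ExpressionMatrix, PermutationConfig,
                     SampleGroups, assign_groups, call_degs, empirical_p,
                     integrated_de, permutation_null, storey_q,
                     stouffer_combine, three_statistics)
from sigloss.io import SiglossError


def matrix_from(rows, genes=None, samples=None, scale="normalized"):
    rows = np.atleast_2d(np.asarray(rows, float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples),
                            scale=scale)


class TestAssignGroups:
    def test_quartile_rule_on_1_to_8(self):
        m = matrix_from([range(1, 9)], genes=["anchor"])
        g = assign_groups(m, "anchor", "quartile_low_vs_rest")
        # Q1 of 1..8 = 2.75; strictly-below samples hold values 1 and 2
        assert sorted(g.low) == ["s0", "s1"]
        assert len(g.high) == 6

    def test_median_rule_even_n_distinct(self):
        m = matrix_from([[5, 1, 9, 3, 7, 11]], genes=["anchor"])
        g = assign_groups(m, "anchor", "below_median")
        assert len(g.low) == 3

    def test_ties_at_threshold_go_high(self):
        m = matrix_from([[1, 2, 2, 2, 8, 8, 8, 9]], genes=["anchor"])
        g = assign_groups(m, "anchor", "quartile_low_vs_rest")
        # Q1 = 2 exactly: the three samples tied at the threshold stay high
        assert sorted(g.low) == ["s0"]
        thr = np.quantile([1, 2, 2, 2, 8, 8, 8, 9], 0.25)
        assert all(m.values.loc["anchor", s] < thr for s in g.low)

    def test_constant_anchor_raises(self):
        m = matrix_from([[2.0] * 8], genes=["anchor"])
        with pytest.raises(SiglossError, match="degenerate"):
            assign_groups(m, "anchor")

    def test_missing_anchor_raises(self):
        m = matrix_from([[1, 2, 3, 4]])
        with pytest.raises(SiglossError, match="nope"):
            assign_groups(m, "nope")


class TestThreeStatistics:
    def test_identical_groups_give_zero(self):
        m = matrix_from([[3, 5, 7, 3, 5, 7]])
        g = SampleGroups(low=["s0", "s1", "s2"], high=["s3", "s4", "s5"])
        st = three_statistics(m, g)
        assert st.loc["g0"].tolist() == [0.0, 0.0, 0.0]

    def test_lmr_is_log2_median_ratio(self):
        m = matrix_from([[2, 4, 8, 1, 2, 4]])
        g = SampleGroups(low=["s0", "s1", "s2"], high=["s3", "s4", "s5"])
        st = three_statistics(m, g)
        assert st.loc["g0", "lmr"] == pytest.approx(1.0)  # log2(4/2)

    def test_ranksum_matches_exhaustive_rank_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(2, 1, 12)
        m = matrix_from([vals])
        low, high = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        st = three_statistics(m, SampleGroups(low=low, high=high))
        # brute-force: rank all log2 values, z from exact mean/variance
        r = rankdata(np.log2(vals + 1))
        w_obs = r[:6].sum()
        n, n1, n2 = 12, 6, 6
        var = n1 * n2 / (n * (n - 1)) * np.sum((r - (n + 1) / 2) ** 2)
        assert st.loc["g0", "w_stat"] == pytest.approx(
            (w_obs - n1 * (n + 1) / 2) / np.sqrt(var))

    def test_zero_variance_gene_yields_zero_t_not_exception(self):
        m = matrix_from([[4.0] * 6])
        g = SampleGroups(low=["s0", "s1", "s2"], high=["s3", "s4", "s5"])
        assert three_statistics(m, g).loc["g0", "t_stat"] == 0.0


class TestEmpiricalP:
    def test_obs_beyond_all_nine_nulls(self):
        assert empirical_p(10.0, np.arange(9)) == pytest.approx(0.2)

    def test_obs_at_null_median_capped_at_one(self):
        assert empirical_p(5.0, np.array([1, 3, 5, 7, 9])) == 1.0

    def test_never_exceeds_one(self):
        assert empirical_p(2.0, np.full(7, 2.0)) == 1.0

    def test_empty_null_raises(self):
        with pytest.raises(SiglossError):
            empirical_p(1.0, np.array([]))


class TestPermutationNull:
    def test_constant_gene_null_all_zero(self):
        m = matrix_from([[2.0] * 6, [1, 2, 3, 4, 5, 6]])
        g = SampleGroups(low=["s0", "s1", "s2"], high=["s3", "s4", "s5"])
        nulls = permutation_null(m, g, PermutationConfig(B=100, seed=1))
        assert np.all(nulls.t[0] == 0) and np.all(nulls.w[0] == 0)
        assert np.all(nulls.lmr[0] == 0)

    def test_seeded_reproducibility(self, toy_matrix, toy_groups):
        a = permutation_null(toy_matrix, toy_groups, PermutationConfig(B=200, seed=9))
        b = permutation_null(toy_matrix, toy_groups, PermutationConfig(B=200, seed=9))
        assert np.array_equal(a.t, b.t) and np.array_equal(a.lmr, b.lmr)

    def test_exhaustive_equals_enumeration_oracle(self):
        """Empirical p in exhaustive mode == brute-force enumeration of all
        C(6,3)=20 label assignments, per statistic and gene."""
        rng = np.random.default_rng(11)
        vals = rng.lognormal(2, 0.8, size=(4, 6))
        m = matrix_from(vals)
        low, high = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        g = SampleGroups(low=low, high=high)
        obs = three_statistics(m, g)
        nulls = permutation_null(m, g, PermutationConfig(B=20, seed=0, exhaustive=True))
        assert nulls.B == 20

        # independent oracle: enumerate assignments, recompute t by hand
        logv = np.log2(vals + 1)
        for gi in range(4):
            null_t = []
            for combo in itertools.combinations(range(6), 3):
                lo = logv[gi, list(combo)]
                hi = logv[gi, [j for j in range(6) if j not in combo]]
                num = lo.mean() - hi.mean()
                den = np.sqrt(lo.var(ddof=1) / 3 + hi.var(ddof=1) / 3)
                null_t.append(num / den if den > 0 else 0.0)
            null_t = np.array(null_t)
            o = obs["t_stat"].iloc[gi]
            # tolerant counting: oracle recomputes t on a different code path
            p_oracle = min(1.0, 2 * (min((null_t >= o - 1e-9).sum(),
                                         (null_t <= o + 1e-9).sum()) + 1) / 21)
            p_impl = empirical_p(obs["t_stat"].iloc[gi], nulls.t[gi])
            assert p_impl == pytest.approx(p_oracle)

    def test_exhaustive_needs_enough_budget(self, toy_matrix, toy_groups):
        with pytest.raises(SiglossError, match="exhaustive"):
            permutation_null(toy_matrix, toy_groups,
                             PermutationConfig(B=50, seed=0, exhaustive=True))


class TestStoufferCombine:
    def test_all_ones_give_zero(self):
        z, p = stouffer_combine([1.0], [1.0], [1.0], [[1.0], [1.0], [1.0]])
        assert z[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_three_equal_one_direction(self):
        z, _ = stouffer_combine([0.05], [0.05], [0.05], [[1.0], [1.0], [1.0]])
        assert z[0] == pytest.approx(norm.ppf(0.975) * np.sqrt(3), abs=1e-4)
        assert z[0] == pytest.approx(3.394, abs=1e-3)

    def test_opposite_directions_cancel(self):
        z, p = stouffer_combine([0.05], [0.05], [1.0], [[1.0], [-1.0], [1.0]])
        assert z[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_bad_sign_vector_raises(self):
        with pytest.raises(SiglossError):
            stouffer_combine([0.5], [0.5], [0.5], [[1.0], [1.0]])

    def test_out_of_range_p_raises(self):
        with pytest.raises(SiglossError):
            stouffer_combine([0.0], [0.5], [0.5], [[1.0], [1.0], [1.0]])


class TestStoreyQ:
    def test_pi0_one_reduces_to_bh(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.01, 0.02, 0.9, 0.95])  # half above lambda=0.5 -> pi0=1
        q = storey_q(p, lam=0.5)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh)

    def test_all_equal_p_all_equal_q(self):
        q = storey_q(np.full(10, 0.3))
        assert np.allclose(q, q[0])

    def test_pi0_capped_at_one(self):
        # every p above lambda: raw estimate 2 -> capped
        q = storey_q(np.linspace(0.6, 0.99, 20))
        assert np.all(q <= 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, 200)
        q = storey_q(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_raises(self):
        with pytest.raises(SiglossError):
            storey_q([0.5, 1.2])


class TestCallDegs:
    def make_stats(self, q, lmr):
        return pd.DataFrame({"q": q, "lmr": lmr},
                            index=[f"g{i}" for i in range(len(q))])

    def test_threshold_edges(self):
        # q=0.04, lmr=0.60 -> up; q=0.04, lmr=0.50 -> excluded
        stats = self.make_stats([0.04, 0.04, 0.04, 0.5], [0.60, 0.50, -0.70, 1.0])
        sig = call_degs(stats, DegCriteria())
        assert sig.up_genes == {"g0"}
        assert sig.down_genes == {"g2"}

    def test_empty_signature_warns(self):
        stats = self.make_stats([0.5], [0.0])
        with pytest.warns(UserWarning, match="empty"):
            sig = call_degs(stats)
        assert len(sig) == 0


class TestPipelineInvariances:
    def test_invariant_to_gene_and_sample_order(self, small_cohort):
        expr, _, _ = small_cohort
        g = assign_groups(expr, "ZFP36")
        cfg = PermutationConfig(B=200, seed=4)
        base = integrated_de(expr, g, cfg)

        rng = np.random.default_rng(0)
        gene_perm = rng.permutation(expr.n_genes)
        samp_perm = rng.permutation(expr.n_samples)
        shuffled = ExpressionMatrix(
            expr.values.iloc[gene_perm, samp_perm], scale=expr.scale)
        g2 = assign_groups(shuffled, "ZFP36")
        out = integrated_de(shuffled, g2, cfg)
        pd.testing.assert_frame_equal(out.sort_index(), base.sort_index())

    def test_calibrated_p_agrees_between_null_modes_in_bulk(self, small_cohort):
        """Pooled and per-gene nulls give concordant DEG calls on real signal."""
        expr, _, truth = small_cohort
        g = assign_groups(expr, "ZFP36")
        pooled = integrated_de(expr, g, PermutationConfig(B=300, seed=4),
                               null_mode="pooled")
        per_gene = integrated_de(expr, g, PermutationConfig(B=300, seed=4),
                                 null_mode="per_gene")
        up_a = set(call_degs(pooled).up_genes)
        up_b = set(call_degs(per_gene).up_genes)
        # planted genes are extreme enough to be called under either null
        assert truth.planted_up <= up_a and truth.planted_up <= up_b
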