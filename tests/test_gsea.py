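"""Running-sum enrichment: ES arithmetic against a brute-force walk,
permutation significance and calibration."""

import numpy as np
import pandas as pd
import pytest

from sigloss import GeneSetCollection, es_significance, rank_genes, running_es
from sigloss.gsea import _es_from_positions
from sigloss.io import SiglossError


def ranked_list(metrics, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(metrics))]
    return rank_genes(pd.Series(metrics, index=genes, dtype=float))


def brute_force_es(ranked, gene_set, weight_exp):
    """Independent oracle: literal position-by-position walk."""
    genes = list(ranked.index)
    metric = ranked.to_numpy(float)
    hits = [g in gene_set for g in genes]
    n, nh = len(genes), sum(hits)
    wsum = sum(abs(metric[i]) ** weight_exp for i in range(n) if hits[i])
    run, best, best_abs = 0.0, 0.0, -1.0
    for i in range(n):
        if hits[i]:
            run += (abs(metric[i]) ** weight_exp / wsum) if wsum > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > best_abs + 1e-15:
            best, best_abs = run, abs(run)
    return best


class TestRunningEs:
    def test_single_top_gene_scores_one(self):
        ranked = ranked_list(np.arange(10, 0, -1))
        es, running, leading = running_es(ranked, {ranked.index[0]})
        assert es == pytest.approx(1.0)
        assert leading == [ranked.index[0]]

    def test_weight_zero_top_block(self):
        ranked = ranked_list(np.arange(10, 0, -1))
        top3 = set(ranked.index[:3])
        es, _, _ = running_es(ranked, top3, weight_exp=0)
        assert es == pytest.approx(1.0)  # three hits before any miss

    def test_weight_zero_bottom_block(self):
        ranked = ranked_list(np.arange(10, 0, -1))
        bottom3 = set(ranked.index[7:])
        es, _, _ = running_es(ranked, bottom3, weight_exp=0)
        assert es == pytest.approx(-1.0)  # seven misses before any hit

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0, 1.5])
    def test_matches_brute_force_walk(self, weight_exp):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            metrics = rng.normal(size=n)
            ranked = ranked_list(metrics)
            size = int(rng.integers(2, n - 1))
            gene_set = set(rng.choice(ranked.index, size=size, replace=False))
            es, _, _ = running_es(ranked, gene_set, weight_exp)
            assert es == pytest.approx(brute_force_es(ranked, gene_set, weight_exp))

    def test_fast_null_path_agrees_with_walk(self):
        rng = np.random.default_rng(23)
        for weight_exp in (0.0, 1.0):
            n = 50
            ranked = ranked_list(rng.normal(size=n))
            w_abs = np.abs(ranked.to_numpy()) ** weight_exp
            for _ in range(30):
                s = int(rng.integers(2, 20))
                pos = np.sort(rng.choice(n, size=s, replace=False))
                genes_at = set(np.asarray(ranked.index)[pos])
                es_walk, _, _ = running_es(ranked, genes_at, weight_exp)
                es_fast = _es_from_positions(pos[None, :], w_abs, n)[0]
                assert es_fast == pytest.approx(es_walk)

    def test_reversal_negates_es_at_weight_zero(self):
        rng = np.random.default_rng(3)
        metrics = rng.normal(size=30)
        ranked = ranked_list(metrics)
        gene_set = set(rng.choice(ranked.index, size=8, replace=False))
        es_fwd, _, _ = running_es(ranked, gene_set, weight_exp=0)
        reversed_ranked = pd.Series(ranked.to_numpy()[::-1] * 0 - np.arange(30),
                                    index=ranked.index[::-1])
        es_rev, _, _ = running_es(reversed_ranked, gene_set, weight_exp=0)
        assert es_rev == pytest.approx(-es_fwd)

    def test_complement_has_opposite_sign_at_weight_zero(self):
        rng = np.random.default_rng(4)
        ranked = ranked_list(rng.normal(size=25))
        gene_set = set(rng.choice(ranked.index, size=7, replace=False))
        comp = set(ranked.index) - gene_set
        es_a, _, _ = running_es(ranked, gene_set, weight_exp=0)
        es_b, _, _ = running_es(ranked, comp, weight_exp=0)
        if abs(es_a) > 1e-12:
            assert np.sign(es_a) == -np.sign(es_b)

    def test_random_sets_mean_es_near_zero(self):
        rng = np.random.default_rng(9)
        n = 200
        ranked = ranked_list(rng.normal(size=n))
        w_abs = np.ones(n)  # weight 0
        draws = np.sort(
            np.argsort(rng.random((3000, n)), axis=1)[:, :15], axis=1)
        es = _es_from_positions(draws, w_abs, n)
        assert abs(es.mean()) < 3 * es.std() / np.sqrt(len(es))

    def test_set_equal_to_universe_raises(self):
        ranked = ranked_list([3, 2, 1])
        with pytest.raises(SiglossError, match="universe"):
            running_es(ranked, set(ranked.index))

    def test_disjoint_set_raises(self):
        ranked = ranked_list([3, 2, 1])
        with pytest.raises(SiglossError, match="intersect"):
            running_es(ranked, {"zz"})


class TestEsSignificance:
    def test_planted_set_recovered_gene_set_mode(self, small_cohort):
        from sigloss import assign_groups, integrated_de, PermutationConfig
        expr, _, truth = small_cohort
        groups = assign_groups(expr, "ZFP36")
        stats = integrated_de(expr, groups, PermutationConfig(B=200, seed=2))
        ranked = rank_genes(stats["lmr"])
        rng = np.random.default_rng(0)
        decoys = {f"DECOY_{i}": list(rng.choice(ranked.index, 20, replace=False))
                  for i in range(5)}
        sets = {"PLANTED_UP": sorted(truth.planted_up), **decoys}
        res = es_significance(ranked, sets, mode="gene_set_perm", n_perm=500, seed=1)
        assert res.loc["PLANTED_UP", "NES"] > 0
        assert res.loc["PLANTED_UP", "q"] < 0.25
        assert bool(res.loc["PLANTED_UP", "significant"])

    def test_phenotype_mode_runs_and_flags_planted(self, small_cohort):
        from sigloss import assign_groups
        expr, _, truth = small_cohort
        groups = assign_groups(expr, "ZFP36")
        sets = {"PLANTED_UP": sorted(truth.planted_up)}
        res = es_significance(None, sets, mode="phenotype_perm", n_perm=50,
                              seed=3, expression=expr, groups=groups)
        assert res.loc["PLANTED_UP", "ES"] > 0
        assert res.loc["PLANTED_UP", "p"] < 0.1

    def test_p_never_zero(self):
        rng = np.random.default_rng(6)
        ranked = ranked_list(rng.normal(size=100))
        sets = {"S": list(ranked.index[:10])}
        res = es_significance(ranked, sets, n_perm=50, seed=0)
        assert (res["p"] > 0).all()

    def test_size_filters_apply(self):
        rng = np.random.default_rng(7)
        ranked = ranked_list(rng.normal(size=100))
        coll = GeneSetCollection({"TINY": list(ranked.index[:3]),
                                  "OK": list(ranked.index[:20])}, min_size=10)
        res = es_significance(ranked, coll, n_perm=50, seed=0)
        assert list(res.index) == ["OK"]

    def test_n_perm_floor(self):
        ranked = ranked_list([3, 2, 1, 0.5])
        with pytest.raises(SiglossError, match="n_perm"):
            es_significance(ranked, {"S": ["g000"]}, n_perm=5)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        ranked = ranked_list(rng.normal(size=80))
        sets = {"A": list(ranked.index[:12]), "B": list(ranked.index[30:45])}
        r1 = es_significance(ranked, sets, n_perm=100, seed=5)
        r2 = es_significance(ranked, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)


def test_rank_genes_deterministic_tie_break():
    s = pd.Series([1.0, 2.0, 1.0], index=["b", "c", "a"])
    ranked = rank_genes(s)
    assert list(ranked.index) == ["c", "a", "b"]  # ties by gene id
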