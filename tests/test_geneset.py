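from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nbsubtype import (combine_z, one_vs_rest_stat, overlap_and_rank,
                       permutation_pvalues, select_dataset_top)

from conftest import make_matrix


def labelled_matrix(rng, n_genes, group_sizes):
    labels = pd.Series(np.repeat([1, 2, 3, 4][: len(group_sizes)], group_sizes))
    labels.index = [f"s{i}" for i in range(len(labels))]
    m = make_matrix(rng.normal(8, 1, (n_genes, len(labels))),
                    samples=list(labels.index))
    return m, labels


class TestOneVsRestStat:
    def test_equal_means_zero_d(self):
        values = np.tile([1.0, 2.0, 1.0, 2.0], (3, 1))
        m = make_matrix(values)
        labels = pd.Series([1, 1, 2, 2], index=m.samples)
        res = one_vs_rest_stat(m, labels, 1)
        np.testing.assert_allclose(res["d"], 0, atol=1e-12)

    def test_s0_zero_equals_pooled_t_oracle(self, rng):
        m, labels = labelled_matrix(rng, 10, (5, 7))
        res = one_vs_rest_stat(m, labels, 1, s0=0.0)
        x = m.data
        g = labels.index[labels == 1]
        r = labels.index[labels == 2]
        for gene in m.genes:
            a, b = x.loc[gene, g].to_numpy(), x.loc[gene, r].to_numpy()
            sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
                / (len(a) + len(b) - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            assert res.loc[gene, "d"] == pytest.approx(t, rel=1e-10)

    def test_doubling_mean_difference_doubles_d(self, rng):
        m, labels = labelled_matrix(rng, 5, (6, 6))
        base = one_vs_rest_stat(m, labels, 1, s0=0.3)
        shifted = m.data.copy()
        diff = base["log2_fc"]
        shifted.loc[:, labels.index[labels == 1]] = \
            shifted.loc[:, labels.index[labels == 1]].add(diff, axis=0)
        m2 = make_matrix(shifted.to_numpy(), genes=m.genes, samples=m.samples)
        res2 = one_vs_rest_stat(m2, labels, 1, s0=0.3)
        # adding the group-mean difference to the group doubles it, variances
        # unchanged, so d doubles at fixed s and s0
        np.testing.assert_allclose(res2["d"], 2 * base["d"], rtol=1e-10)

    def test_small_group_rejected(self, rng):
        m, labels = labelled_matrix(rng, 5, (1, 6))
        with pytest.raises(ValueError, match="fewer than 2"):
            one_vs_rest_stat(m, labels, 1)


class TestPermutationPvalues:
    def test_extreme_gene_hits_add_one_floor(self, rng):
        m, labels = labelled_matrix(rng, 1, (5, 15))
        data = m.data.copy()
        data.loc[:, labels.index[labels == 1]] += 1000.0
        m = make_matrix(data.to_numpy(), genes=m.genes, samples=m.samples)
        res = permutation_pvalues(m, labels, 1, n_perm=99, seed=0)
        assert res["perm_p"].iloc[0] == pytest.approx(1 / 100)

    def test_pvalues_bounded(self, rng):
        m, labels = labelled_matrix(rng, 50, (6, 6))
        res = permutation_pvalues(m, labels, 1, n_perm=50, seed=1)
        assert (res["perm_p"] >= 1 / 51 - 1e-12).all()
        assert (res["perm_p"] <= 1.0 + 1e-12).all()

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        m, labels = labelled_matrix(rng, 6, (2, 2))
        s0 = 0.1
        res = permutation_pvalues(m, labels, 1, s0=s0, exhaustive=True)

        # independent oracle: enumerate all 6 splits with the textbook formula
        x = m.data.to_numpy()
        d_star = []
        for idx in combinations(range(4), 2):
            mask = np.zeros(4, dtype=bool)
            mask[list(idx)] = True
            a, b = x[:, mask], x[:, ~mask]
            sp2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
            se = np.sqrt(sp2 * (1 / 2 + 1 / 2))
            d_star.append(np.abs((a.mean(axis=1) - b.mean(axis=1)) / (se + s0)))
        pooled = np.concatenate(d_star)
        obs = np.abs(one_vs_rest_stat(m, labels, 1, s0=s0)["d"].to_numpy())
        count = (pooled[None, :] >= obs[:, None] * (1 - 1e-9) - 1e-12).sum(axis=1)
        expected = (1 + count / 6) / (6 + 1)
        np.testing.assert_allclose(res["perm_p"], expected, rtol=1e-12)

    def test_identical_seed_identical_pvalues(self, rng):
        m, labels = labelled_matrix(rng, 20, (5, 9))
        r1 = permutation_pvalues(m, labels, 1, n_perm=40, seed=7)
        r2 = permutation_pvalues(m, labels, 1, n_perm=40, seed=7)
        pd.testing.assert_frame_equal(r1, r2)


class TestSelectDatasetTop:
    def _stats(self, fc, p=None):
        genes = [f"g{i}" for i in range(len(fc))]
        return pd.DataFrame({
            "d": np.asarray(fc) * 2.0,
            "log2_fc": fc,
            "perm_p": p if p is not None else np.linspace(0.001, 0.05, len(fc)),
        }, index=genes)

    def test_fc_boundary_strict(self):
        stats = self._stats([1.0, 1.0001, 2.0, -3.0, 0.5])
        out = select_dataset_top(stats, top_n=10, fc_log2_threshold=1.0)
        assert "g0" not in out          # exactly 2-fold is excluded
        assert set(out) == {"g1", "g2", "g3"}

    def test_top_n_larger_than_gene_count(self):
        stats = self._stats([2.0, 3.0])
        assert set(select_dataset_top(stats, top_n=100)) == {"g0", "g1"}

    def test_rank_by_p_before_fc_filter(self):
        # the significance cut happens before the fold-change filter
        stats = self._stats([5.0, 2.0, 2.0], p=[0.9, 0.001, 0.002])
        out = select_dataset_top(stats, top_n=2, fc_log2_threshold=1.0)
        assert out == ["g1", "g2"]      # g0 (big FC, bad p) misses the cut


class TestOverlapAndRank:
    def _stats_for(self, genes, fcs):
        return pd.DataFrame({"d": np.asarray(fcs) * 2, "log2_fc": fcs,
                             "perm_p": 0.01}, index=genes)

    def test_intersection(self):
        genes1, genes2 = list("ABC"), list("BCD")
        lists1 = {c: genes1 for c in (1, 2, 3, 4)}
        lists2 = {c: genes2 for c in (1, 2, 3, 4)}
        stats1 = {c: self._stats_for(genes1, [3.0, 2.0, 1.5]) for c in (1, 2, 3, 4)}
        stats2 = {c: self._stats_for(genes2, [3.0, 2.5, 1.5]) for c in (1, 2, 3, 4)}
        gs = overlap_and_rank([lists1, lists2], [stats1, stats2], 30)
        assert set(gs.per_contrast[1]) == {"B", "C"}

    def test_combined_fc_is_mean(self):
        lists = [{1: ["A"]}, {1: ["A"]}]
        stats = [{1: self._stats_for(["A"], [2.0])},
                 {1: self._stats_for(["A"], [3.0])}]
        gs = overlap_and_rank(lists, stats, 30)
        assert gs.combined_fc[1]["A"] == pytest.approx(2.5)

    def test_union_dedup_mirrors_120_to_98(self):
        # 4 contrasts x 30 genes with 22 duplicates -> 98 unique genes
        contrast_genes = {
            1: [f"u{i:03d}" for i in range(30)],
            2: [f"u{i:03d}" for i in range(30, 60)],
            3: [f"u{i:03d}" for i in range(60, 90)],
            4: [f"u{i:03d}" for i in range(68, 90)] + [f"u{i:03d}" for i in range(90, 98)],
        }
        lists = [contrast_genes, contrast_genes]
        stats = [{c: self._stats_for(g, np.linspace(5, 2, 30)) for c, g in contrast_genes.items()}
                 for _ in range(2)]
        gs = overlap_and_rank(lists, stats, 30)
        assert sum(len(v) for v in gs.per_contrast.values()) == 120
        assert len(gs.union) == 98

    def test_symmetric_in_dataset_order(self, rng):
        genes = [f"g{i}" for i in range(40)]
        lists1 = {c: genes[:25] for c in (1, 2, 3, 4)}
        lists2 = {c: genes[10:] for c in (1, 2, 3, 4)}
        s1 = {c: self._stats_for(genes, rng.normal(0, 3, 40)) for c in (1, 2, 3, 4)}
        s2 = {c: self._stats_for(genes, rng.normal(0, 3, 40)) for c in (1, 2, 3, 4)}
        a = overlap_and_rank([lists1, lists2], [s1, s2], 10)
        b = overlap_and_rank([lists2, lists1], [s2, s1], 10)
        assert a.per_contrast == b.per_contrast


class TestCombineZ:
    def test_single_dataset_identity(self):
        p = 0.04
        z = combine_z([p], [1.0], [20])
        assert z == pytest.approx(norm.isf(p / 2))

    def test_two_equal_datasets(self):
        p = 2 * norm.sf(1.96)
        z = combine_z([p, p], [1.0, 1.0], [25, 25])
        assert z == pytest.approx(1.96 * np.sqrt(2), rel=1e-9)

    def test_weights_square_sum_to_one(self):
        n = np.array([17, 30])
        w = np.sqrt(n / n.sum())
        assert w @ w == pytest.approx(1.0, abs=1e-12)
        # opposing equal-size signals cancel
        p = 0.01
        assert combine_z([p, p], [1.0, -1.0], [10, 10]) == pytest.approx(0.0)

    def test_extreme_p_clamped(self):
        z = combine_z([0.0], [1.0], [10])
        assert np.isfinite(z)

    def test_vectorized(self):
        p1, p2 = np.array([0.05, 0.5]), np.array([0.01, 0.9])
        z = combine_z([p1, p2], [np.array([1, -1]), np.array([1, 1])], [17, 30])
        assert z.shape == (2,)
        expect0 = (np.sqrt(17 / 47) * norm.isf(0.025)
                   + np.sqrt(30 / 47) * norm.isf(0.005))
        assert z[0] == pytest.approx(expect0)
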