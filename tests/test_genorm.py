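import math

import numpy as np
import pandas as pd
import pytest

import refstab as rs
from conftest import naive_genorm_order, naive_pairwise_sd


def qmatrix(rows, group_of=None):
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    return rs.QuantityMatrix(values,
                             {g: 1.0 for g in values.index},
                             group_of or {c: "G" for c in values.columns})


class TestPairwiseVariation:
    def test_proportional_genes_have_zero_variation(self):
        q = qmatrix({"a": [0.2, 0.5, 1.0], "b": [0.1, 0.25, 0.5]})
        assert rs.pairwise_gene_variation(q, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sd(self):
        # log2 ratios are (0, 1): sample SD = sqrt(0.5)
        q = qmatrix({"a": [1.0, 1.0], "b": [1.0, 0.5]})
        assert rs.pairwise_gene_variation(q, "a", "b") == pytest.approx(
            math.sqrt(0.5), abs=1e-12)

    def test_symmetry_and_loop_oracle(self):
        rng = np.random.default_rng(23)
        rows = {"a": rng.uniform(0.05, 1.0, 6), "b": rng.uniform(0.05, 1.0, 6)}
        q = qmatrix(rows)
        v = rs.pairwise_gene_variation(q, "a", "b")
        assert v == pytest.approx(rs.pairwise_gene_variation(q, "b", "a"))
        assert v == pytest.approx(naive_pairwise_sd(rows["a"], rows["b"]),
                                  rel=1e-12)

    def test_insufficient_common_samples(self):
        values = pd.DataFrame({"s0": [1.0, 0.5], "s1": [0.7, np.nan],
                               "s2": [0.6, np.nan]},
                              index=["a", "b"])
        q = rs.QuantityMatrix(values, {"a": 1.0, "b": 1.0},
                              {f"s{i}": "G" for i in range(3)})
        with pytest.raises(rs.InsufficientDataError):
            rs.pairwise_gene_variation(q, "a", "b")


class TestMValues:
    def test_two_proportional_genes_share_zero_m(self):
        q = qmatrix({"a": [0.2, 0.4, 0.8], "b": [0.1, 0.2, 0.4]})
        m = rs.m_values(q)
        assert m["a"] == pytest.approx(0.0, abs=1e-12)
        assert m["b"] == pytest.approx(m["a"])

    def test_proportional_pair_beats_noisy_gene(self, small_quantities):
        m = rs.m_values(small_quantities)
        assert m["A"] == pytest.approx(m["B"], abs=1e-12)
        assert m["C"] > m["A"]

    def test_mean_of_pairwise_variations(self):
        rng = np.random.default_rng(29)
        rows = {g: rng.uniform(0.05, 1.0, 6) for g in "abcd"}
        q = qmatrix(rows)
        m = rs.m_values(q)
        for j in "abcd":
            expected = np.mean([naive_pairwise_sd(rows[j], rows[k])
                                for k in "abcd" if k != j])
            assert m[j] == pytest.approx(expected, rel=1e-12)

    def test_singleton_rejected(self):
        q = qmatrix({"a": [1.0, 0.5, 0.7]})
        with pytest.raises(ValueError):
            rs.m_values(q, ["a"])


class TestRankGenorm:
    def test_planted_noisy_pair_excluded_first(self, planted_quantities):
        q, truth = planted_quantities
        res = rs.rank_genorm(q)
        stable, unstable = set(truth.labelled("stable")), set(truth.labelled("unstable"))
        assert set(res.exclusion_order[: len(unstable)]) == unstable
        assert set(res.ranking[: len(stable)]) == stable

    def test_three_genes_single_step(self, small_quantities):
        res = rs.rank_genorm(small_quantities)
        assert res.exclusion_order == ["C"]
        assert res.tied_pair == ("A", "B")
        assert res.m_at_exclusion["A"] == res.m_at_exclusion["B"]
        assert res.m_at_exclusion["A"] == pytest.approx(
            rs.pairwise_gene_variation(small_quantities, "A", "B"))

    @pytest.mark.parametrize("n_genes", [4, 5])
    @pytest.mark.parametrize("seed", range(10))
    def test_stepwise_order_matches_brute_force(self, n_genes, seed):
        rng = np.random.default_rng(1000 + seed)
        rows = {f"g{i}": rng.uniform(0.05, 1.0, 8) for i in range(n_genes)}
        q = qmatrix(rows)
        res = rs.rank_genorm(q)
        excl, pair, m_at = naive_genorm_order(rows)
        assert res.exclusion_order == excl
        assert res.tied_pair == tuple(pair)
        for g in rows:
            assert res.m_at_exclusion[g] == pytest.approx(m_at[g], rel=1e-9)

    def test_m_at_exclusion_column_is_monotone(self, planted_quantities):
        q, _ = planted_quantities
        res = rs.rank_genorm(q)
        ms = [res.m_at_exclusion[g] for g in res.ranking]
        assert ms[0] == ms[1]
        assert all(a <= b + 1e-12 for a, b in zip(ms[1:], ms[2:]))


class TestNfPairwiseVariation:
    def test_mutually_proportional_genes_give_zero_v(self):
        base = np.array([0.2, 0.5, 0.9, 0.4])
        q = qmatrix({"a": base, "b": base * 0.5, "c": base * 0.25,
                     "d": base * 0.8})
        res = rs.rank_genorm(q)
        assert np.allclose(res.pairwise_variations, 0.0, atol=1e-12)

    def test_loop_oracle_five_genes(self):
        rng = np.random.default_rng(31)
        rows = {f"g{i}": rng.uniform(0.05, 1.0, 7) for i in range(5)}
        q = qmatrix(rows)
        ranking = rs.rank_genorm(q).ranking
        vs = rs.nf_pairwise_variation(q, ranking)
        import statistics
        for n in range(2, 5):
            nf_n = [math.prod(rows[g][s] for g in ranking[:n]) ** (1 / n)
                    for s in range(7)]
            nf_n1 = [math.prod(rows[g][s] for g in ranking[: n + 1]) ** (1 / (n + 1))
                     for s in range(7)]
            expected = statistics.stdev(math.log2(a / b)
                                        for a, b in zip(nf_n, nf_n1))
            assert vs[n - 2] == pytest.approx(expected, rel=1e-9)


class TestOptimalGeneCount:
    @pytest.mark.parametrize("v,expected", [
        ([0.10], 2),
        ([0.2, 0.18, 0.12], 4),
        ([0.2, 0.2, 0.2], 5),        # nothing below cutoff: all genes, warned
    ])
    def test_cutoff_rule(self, v, expected):
        assert rs.optimal_gene_count(v, cutoff=0.15) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            rs.optimal_gene_count([])


class TestInvariances:
    @pytest.mark.parametrize("c", [0.01, 0.5, 7.0])
    def test_m_invariant_to_per_gene_scaling(self, c, small_quantities):
        q = small_quantities
        scaled = rs.QuantityMatrix(
            q.values.mul(pd.Series({"A": c, "B": 1.0, "C": 1.0}), axis=0),
            dict(q.efficiency_of), dict(q.group_of))
        m0, m1 = rs.m_values(q), rs.m_values(scaled)
        for g in m0:
            assert m1[g] == pytest.approx(m0[g], abs=1e-9)

    def test_m_invariant_to_sample_permutation(self, small_quantities):
        q = small_quantities
        perm = list(reversed(q.samples))
        shuffled = rs.QuantityMatrix(q.values[perm], dict(q.efficiency_of),
                                     dict(q.group_of))
        m0, m1 = rs.m_values(q), rs.m_values(shuffled)
        for g in m0:
            assert m1[g] == pytest.approx(m0[g], abs=1e-12)
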